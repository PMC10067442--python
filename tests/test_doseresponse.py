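import numpy as np
import pandas as pd
import pytest

import nemascreen as ns
from nemascreen.doseresponse import FitConstraints, TitrationSeries, fits_to_frame, hill_curve


def _series(conc, activity, n=None, cpd="c1"):
    return TitrationSeries(cpd, "gfp_area_total", 7, np.asarray(conc),
                           np.asarray(activity),
                           np.ones(len(conc)) if n is None else np.asarray(n))


def _norm_frame(compounds, concs, activity_fn):
    rows = []
    for cpd in compounds:
        for k, c in enumerate(concs):
            rows.append({"plate_id": f"P{k+1:02d}", "well": "A03", "day": 7,
                         "role": "sample", "compound_id": cpd, "conc_m": c,
                         "readout": "gfp_area_total",
                         "activity_pct": activity_fn(cpd, c)})
    return pd.DataFrame(rows)


class TestAssembly:
    def test_bookkeeping_643_by_7_gives_4501_points(self, seven_point_concs):
        compounds = [f"C{i:03d}" for i in range(643)]
        norm = _norm_frame(compounds, seven_point_concs, lambda cpd, c: 0.0)
        series = ns.assemble_series(norm)
        assert len(series) == 643
        assert all(len(s) == 7 for s in series)
        assert sum(len(s) for s in series) == 4501

    def test_eleven_point_intraplate_series(self):
        concs = 50e-6 / 3.0 ** np.arange(10, -1, -1)
        norm = _norm_frame(["c"], concs, lambda cpd, c: 0.0)
        (s,) = ns.assemble_series(norm)
        assert len(s) == 11

    def test_duplicate_concentrations_averaged(self):
        norm = pd.concat([
            _norm_frame(["c"], [1e-6, 1e-5], lambda cpd, c: -20.0),
            _norm_frame(["c"], [1e-6, 1e-5], lambda cpd, c: -40.0),
        ])
        (s,) = ns.assemble_series(norm)
        assert s.activity == pytest.approx([-30.0, -30.0])
        assert list(s.n) == [2, 2]

    def test_single_concentration_excluded_with_warning(self):
        norm = _norm_frame(["lonely"], [1e-6], lambda cpd, c: -50.0)
        with pytest.warns(UserWarning, match="lonely"):
            series = ns.assemble_series(norm)
        assert series == []

    def test_concentrations_strictly_increasing(self):
        with pytest.raises(ValueError):
            _series([1e-6, 1e-6], [0, 0])


class TestHillFit:
    def test_noiseless_identity_recovery(self, seven_point_concs):
        """Noiseless 4PL points return the generating parameters to 0.1%."""
        true = dict(bottom=-100.0, top=0.0, log_ec50=-6.0, hill_slope=-1.0)
        y = hill_curve(np.log10(seven_point_concs), **true)
        fit = ns.fit_hill(_series(seven_point_concs, y))
        assert fit.converged
        assert fit.bottom == pytest.approx(true["bottom"], rel=1e-3, abs=1e-3)
        assert fit.top == pytest.approx(true["top"], abs=1e-3)
        assert fit.log_ec50 == pytest.approx(true["log_ec50"], rel=1e-3)
        assert fit.hill_slope == pytest.approx(true["hill_slope"], rel=1e-3)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_series_inactive_outcome(self, seven_point_concs):
        fit = ns.fit_hill(_series(seven_point_concs, np.zeros(7)))
        if fit.converged:
            assert abs(fit.top - fit.bottom) * 1 <= 1e-3 or abs(
                hill_curve(np.log10(seven_point_concs[-1]), fit.bottom, fit.top,
                           fit.log_ec50, fit.hill_slope)
                - hill_curve(np.log10(seven_point_concs[0]), fit.bottom, fit.top,
                             fit.log_ec50, fit.hill_slope)) <= 1e-3

    def test_stochastic_recovery_levamisole_like(self, seven_point_concs):
        """Median |log EC50 error| <= 0.1 at 5% noise over 100 seeds."""
        logc = np.log10(seven_point_concs)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = hill_curve(logc, -100, 0, -5.8, -1.5) + rng.normal(0, 5, 7)
            fit = ns.fit_hill(_series(seven_point_concs, y))
            errs.append(abs(fit.log_ec50 - (-5.8)))
        assert np.median(errs) <= 0.1

    def test_bias_small_over_ec50_grid(self, seven_point_concs):
        """|bias of log EC50| <= 0.05 at 5% noise across interior EC50s,
        among fits not flagged extrapolated (the flag exists precisely to
        exclude EC50s the tested range cannot support)."""
        logc = np.log10(seven_point_concs)
        for le_true in (-7.5, -6.5, -5.5):
            errs = []
            for seed in range(100):
                rng = np.random.default_rng(1000 + seed)
                y = hill_curve(logc, -100, 0, le_true, -1.0) + rng.normal(0, 5, 7)
                fit = ns.fit_hill(_series(seven_point_concs, y))
                if not fit.extrapolated:
                    errs.append(fit.log_ec50 - le_true)
            assert len(errs) >= 90
            assert abs(np.mean(errs)) <= 0.05, le_true

    def test_unit_rescaling_shifts_log_ec50_only(self, seven_point_concs):
        y = hill_curve(np.log10(seven_point_concs), -100, 0, -6.0, -1.2)
        f_molar = ns.fit_hill(_series(seven_point_concs, y))
        f_micromolar = ns.fit_hill(_series(seven_point_concs * 1e6, y))
        assert f_micromolar.log_ec50 == pytest.approx(f_molar.log_ec50 + 6, abs=1e-6)
        assert f_micromolar.hill_slope == pytest.approx(f_molar.hill_slope, rel=1e-4)
        assert f_micromolar.top == pytest.approx(f_molar.top, abs=1e-4)

    def test_direction_matches_data(self, seven_point_concs):
        y = hill_curve(np.log10(seven_point_concs), -100, 0, -6.0, -1.0)
        fit = ns.fit_hill(_series(seven_point_concs, y))
        assert fit.hill_slope < 0
        lo = hill_curve(np.log10(seven_point_concs[0]), fit.bottom, fit.top,
                        fit.log_ec50, fit.hill_slope)
        hi = hill_curve(np.log10(seven_point_concs[-1]), fit.bottom, fit.top,
                        fit.log_ec50, fit.hill_slope)
        assert hi < lo

    def test_extrapolated_ec50_flagged(self, seven_point_concs):
        # half-effect far above the tested range: only the curve's toe is seen
        y = hill_curve(np.log10(seven_point_concs), -100, 0, -3.0, -1.0)
        fit = ns.fit_hill(_series(seven_point_concs, y))
        if fit.converged and np.isfinite(fit.log_ec50):
            assert fit.extrapolated or fit.log_ec50 > np.log10(seven_point_concs).max()

    def test_three_point_series_uses_fixed_bottom(self):
        conc = np.array([1e-7, 1e-6, 1e-5])
        y = hill_curve(np.log10(conc), -100, 0, -6.0, -1.0)
        fit = ns.fit_hill(_series(conc, y))
        assert fit.converged
        assert fit.bottom == pytest.approx(-100.0)

    def test_replicate_weights_pull_fit(self, seven_point_concs):
        y = hill_curve(np.log10(seven_point_concs), -100, 0, -6.0, -1.0)
        y_bad = y.copy()
        y_bad[3] += 40.0
        heavy = _series(seven_point_concs, y_bad, n=[9, 9, 9, 1, 9, 9, 9])
        light = _series(seven_point_concs, y_bad)
        f_heavy = ns.fit_hill(heavy)
        f_light = ns.fit_hill(light)
        assert abs(f_heavy.log_ec50 - (-6.0)) <= abs(f_light.log_ec50 - (-6.0)) + 1e-9


class TestMasking:
    def test_clean_series_unmasked(self, seven_point_concs):
        y = hill_curve(np.log10(seven_point_concs), -100, 0, -6.0, -1.0)
        s = _series(seven_point_concs, y)
        fit = ns.mask_outliers(s, ns.fit_hill(s))
        assert fit.masked_points == ()

    def test_spiked_point_masked(self, seven_point_concs):
        rng = np.random.default_rng(2)
        y = hill_curve(np.log10(seven_point_concs), -100, 0, -6.0, -1.5)
        y += rng.normal(0, 2, 7)
        y[2] += 60.0  # 30x the noise SD
        s = _series(seven_point_concs, y)
        fit = ns.mask_outliers(s, ns.fit_hill(s))
        assert 2 in fit.masked_points

    def test_mask_cap_two_points(self, seven_point_concs):
        rng = np.random.default_rng(3)
        y = hill_curve(np.log10(seven_point_concs), -100, 0, -6.0, -1.5)
        y += rng.normal(0, 1, 7)
        y[[1, 3, 5]] += 80.0
        s = _series(seven_point_concs, y)
        fit = ns.mask_outliers(s, ns.fit_hill(s))
        assert len(fit.masked_points) <= 2


def test_fit_frame_export(seven_point_concs):
    y = hill_curve(np.log10(seven_point_concs), -100, 0, -6.0, -1.0)
    s = _series(seven_point_concs, y)
    frame = fits_to_frame([s], [ns.fit_hill(s)])
    assert frame.iloc[0]["ec50_m"] == pytest.approx(1e-6, rel=1e-3)
    assert set(frame.columns) >= {"compound_id", "bottom", "top", "log_ec50",
                                  "ec50_m", "hill_slope", "r2", "converged"}
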