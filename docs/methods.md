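# Methods

This note documents the models behind each pipeline stage, the default
parameters and why they were chosen, and what the synthetic data do and do
not establish about real screens.

## Screen design

The generator reproduces the geometry of a 384-well worm-viability qHTS:

- 16 × 24 plates, wells `A01…P24`. Column 1 is DMSO vehicle (neutral
  control); column 2 is the levamisole toxicity control — rows A–H at the
  fixed full-kill concentration (10 mM stock / 240-fold in-well dilution =
  41.7 µM) and rows I–P as an eight-point 1:3 titration from 10 mM stock
  (down to 4.57 µM stock). Columns 3–24 hold 352 sample wells.
- Inter-plate titration: plate *k* carries every library compound at stock
  `top_stock / dilution_factor^k` (defaults 10 mM, 1:5, seven points), and
  the final concentration is the stock divided by the in-well dilution
  (240). A library larger than 352 splits each concentration point across
  as many plates as needed (suffixes `a`, `b`, …); a strict single-plate
  mode errors instead.
- Unassigned sample wells are carried as additional vehicle wells.

## Population model

Each well runs an independent stage-structured chain
(egg → L1 → L2 → L3 → L4 → adult) on a daily time step:

- Eggs hatch after one day. Hatched worms advance 1 + Bernoulli-rate-1/3
  stages per day, so L1 → adult averages three days — one life cycle — and
  seven days cover more than two cycles.
- Advancement is applied at the cohort level (proportional split with
  stochastic rounding) rather than as independent per-worm draws. Real
  larval development is synchronized to within hours; per-worm draws at
  day resolution add artificial timing dispersion that compounds through
  reproduction and pushes well-to-well variability far above what the
  assay's plate statistics show. With cohort advancement, default plates
  give day-7 GFP-area Z′ ≈ 0.75 (passing the conventional 0.5 screen
  threshold in essentially all replicates), which is the regime a
  successful day-7 screen reports. Kill draws remain per-worm binomial and
  broods remain Poisson, so demographic noise is still present.
- Adults lay `Poisson(adults × brood)` eggs per day, capped by a per-well
  carrying capacity. Defaults: 10 synchronized L1 seeded per well (the
  screen's seeding density), brood 20 eggs/adult/day (a food-limited well,
  well below the ad-libitum ~100+/day), capacity 20,000 (the ceiling of
  the life-stage heat-map scale). Vehicle wells grow to roughly 4,000–5,000
  animals by day 7.
- Compound effect is a per-worm, per-day kill hazard
  `efficacy · stage_susceptibility · c^h / (c^h + EC50^h)` at the well's
  final concentration. The hazard acts daily, so endpoint day-7 curves are
  4PL-shaped with an apparent EC50 below the instantaneous-hazard EC50
  (cumulative exposure plus lost reproduction); recovery tests therefore
  score *ranking and classification* against truth, and exact EC50
  recovery is asserted only on directly generated curves.
- All randomness flows from one seed; each well's substream is derived by
  hashing (plate_id, well), so a well's trajectory is independent of what
  else is simulated.

## Synthetic libraries

Actives (`⌊active_fraction · n⌋` of them, exactly) draw log-uniform EC50s
over 50 nM–5 µM final in-well — inside the 2.67 nM–41.7 µM tested range, so
most planted curves are completable — with efficacies 0.7–1.0 and a slope
mixture of graded (1–2.5) and steep (4–8, avermectin-like) Hill
coefficients. Inactives have efficacy 0. Fingerprints are 729-bit vectors
with a disjoint shared on-bit block per chemotype cluster plus per-compound
noise bits; `n_active_chemotypes` optionally concentrates the actives into
a subset of clusters, emulating libraries where toxicity tracks chemotype.

## Optics and flow models

LSC features are per-stage log-normals with means well inside the published
gate (e.g. areas 2,000 µm² for L1 up to 70,000 µm² for adults, CV 25%) and
monotone in stage; debris is Poisson per well with sub-gate means, so
≥ 99% of worm objects pass the default gate and ≥ 99% of debris fails.
COPAS (TOF, EC) clouds are correlated bivariate log-normals with stage
means spaced geometrically (factor 2, CV 10%); the default stage gates are
±35% rectangles around each mean, pairwise disjoint, leaving ≲ 0.5% of
events unclassified. Because no instrument units for TOF/EC gates are
published, these gates are calibrated to the synthetic flow model and are
fully configurable.

## Plate statistics and normalization

S/B, S/N and Z′ use the standard convention (µ = mean, σ = sample SD,
n−1). S/N combines control SDs in quadrature by default; the
`(µn − µp)/σn` form is available. Positive controls for statistics and
normalization are the column-2 wells at the single full-kill concentration;
the 1:3 titration wells are excluded (they are a per-plate control curve,
not a control population). Undefined statistics (zero denominators) are
reported as NaN so one bad plate cannot abort a run.

## Curve fitting

The variable-slope 4PL is fitted on log₁₀ molar concentration with bounded
least squares (trust-region reflective, analytic Jacobian), points weighted
by replicate count. Numerical choices:

- Initialization from extreme-concentration medians and the half-effect
  crossing; three deterministic slope starts (×1, ×3, ×0.3 of the
  direction-based unit slope). A series whose activity span is under 20%
  has no slope structure worth a multi-start and gets a single bounded
  start with a tighter iteration cap.
- Bounds: bottom ∈ [−120, 20]%, top ∈ [−20, 120]%, |slope| ∈ [0.1, 15],
  log EC50 within the tested range ± 2 decades.
- Series with fewer than four points fall back to a three-parameter fit
  with the bottom fixed at −100% (full kill).
- Outlier masking removes, one at a time, the worst point whose absolute
  residual exceeds 3 robust SDs (1.4826 × MAD — an RMS scale lets a single
  gross outlier hide itself on a 7-point series), refits, and stops at two
  masked points for a 7-point series.
- EC50s outside the tested range are flagged `extrapolated`; recovery
  summaries exclude flagged fits, which is what the flag is for.
- Non-convergence sets `converged=False`; it never raises.

Under 5% activity noise the fitter recovers log EC50 with median absolute
error ≈ 0.05 for graded slopes and |bias| ≤ 0.05 across the range interior.

## Curve classification

Class 1 requires both fitted plateaus supported by a tested point (within
15% of the fitted span), r² ≥ 0.9 and efficacy ≥ the activity floor;
class 2 one plateau; class 3 covers poor fits with real efficacy and
top-concentration-only activity; class 4 is inactive. Sub-class .1/.2
splits at 80% efficacy. The activity floor is
`max(30%, 3 × SD of neutral-control activity)` — on default simulations the
neutral SD is ~5%, so the floor is typically 30%. The screen is
loss-of-signal, so active classes are negative; gain-of-signal handling is
symmetric. These thresholds live in one config block because the upstream
software's exact values are not published; they are stated assumptions.

Follow-up prioritization: tier 1 = high-quality class (−1.1/−1.2/−2.1) on
day 3 and active on day 7; tier 2 = moderate day-3 class (−2.2/−3) with
day-7 activity; tier 3 = day-7 only; tier 4 = inactive; within tiers,
counter-screen-inactive compounds first, then compound id.

## Chemotype SOM and enrichment

Batch SOM on a rectangular grid: nearest-prototype winners (Euclidean on
0/1 vectors), Gaussian neighborhood with radius decaying linearly from
max(rows, cols)/2 to 0.5 over 30 epochs, deterministic per seed. The
default square grid has ≈ 6.5·√N units (14 × 14 for N ≈ 900), sized so
occupied-unit counts land in the ~190-cluster regime reported for
~900-compound chemotype maps. Occupied units are clusters `k<row>.<col>`.

Enrichment per occupied cluster: Welch two-sample t-test of member
log-AC50 against the whole library (a leave-cluster-out option exists),
with inactives imputed at log₁₀(2 × top tested concentration). The signed
score is −log₁₀ p, positive when members are more potent than the library
mean; singleton clusters are reported untestable. Under a fully null
potency vector the fraction of clusters at p < 0.05 stays at the nominal
5% (checked over 200 seeded replicates), and the t-test agrees with a
label-shuffle permutation oracle on constructed cases.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the screen at its native
scale — 643 compounds × 7 concentrations (4501 dose–response points, 14
plates) with 83 planted actives — simulated over the full 7 days with
events emitted for the analysis day(s); the chemotype demo uses 887
compounds on a 14 × 14 map. Stochastic properties use 100–200 seeded
replicates at the sizes stated in each test.

## Known limitations

- No natural (compound-independent) mortality, no male/hermaphrodite
  genetics, no food-depletion dynamics, no pharmacokinetics: concentration
  is constant and the hazard memoryless.
- Day-3 plate quality in simulation is similar to day 7, whereas real
  day-3 statistics are weaker; the generator does not model early-read
  instrument noise floors.
- Egg-stage objects are not emitted (embryonic GFP is ignored), so "living
  worms" in event-count invariants means hatched stages.
- Fingerprints are synthetic bit patterns with planted cluster structure,
  not substructure descriptors computed from molecules; SOM results
  demonstrate algorithmic behaviour, not chemistry.
- Passing recovery tests shows the pipeline is correct and well calibrated
  under the generator's assumptions (log-normal optics, independent wells,
  4PL-consistent truth); it does not certify performance on real plates
  with spatial artefacts, carry-over or edge effects, which the QC module
  deliberately does not model.
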