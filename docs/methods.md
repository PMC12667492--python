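# Methods

## The optimization problem

A one-pot enzyme@CaIDC synthesis is parameterized by three final
concentrations in a 0.5 mL aqueous reaction: Ca²⁺ (mM), deprotonated
4,5-imidazoledicarboxylate ligand (mM), and enzyme (mg/mL). The campaign
treats the space as a finite grid and seeks the recipe maximizing either the
encapsulation efficiency EE (protein-only campaigns) or the performance index
PI = EE × REA (enzyme campaigns, where activity must be retained as well as
mass). Because each trial is a day of bench work, the loop is an
active-learning design-of-experiments: seed broadly, model, propose, measure,
repeat.

## Design grid

Default axes: Ca 2–98 mM in 17 levels (step 6 mM), ligand 22.5–122.5 mM in
101 levels (step 1 mM), enzyme 0.2–1.96 mg/mL in 103 even levels (step
1.76/102 ≈ 0.01725 mg/mL), giving 176,851 combinations. The level counts are
chosen because 176,851 factors uniquely as 17 × 101 × 103 over these ranges,
with the first two factors matching clean steps of 6 and 1 mM; the enzyme
axis is therefore declared by level count rather than by a round increment.
Axes are configurable by `step` or `n_levels`; the span must close exactly on
both bounds (checked to 1e-9).

Recipes are expressed as final concentrations, not stock volumes, because the
surrogate and acquisition operate on the concentration vector. Conversion to
integer-µL pipetting plans (component volume = conc × V_total / stock,
rounded to 1 µL, water as balance) is exact to within half a pipetting
increment per axis. A deliberate caveat: with the documented stocks (100 mM
Ca, 125 mM ligand, 2 mg/mL enzyme in 500 µL) only ~9% of the grid is
physically pipettable — e.g. 98 mM Ca alone needs 490 of the 500 µL. The
package therefore raises `InfeasibleRecipeError` per recipe on conversion and
offers an opt-in `check_feasibility` grid audit, rather than refusing to
construct the (documented) space. Campaigns over concentrations are
unaffected; bench execution of extreme recipes would need more concentrated
stocks.

## Assay reduction

* **BCA calibration** — ordinary least squares through ≥3
  (concentration, absorbance) standards; inversion clips negative
  concentrations to zero with a warning.
* **EE** — 100 × (m_used − c_sup·V_sup)/m_used, clipped to [0, 100] because
  assay noise can push the supernatant estimate past the input mass. Before
  clipping, EE plus the residual percentage is exactly 100.
* **Initial rate** — OLS slope over the first 60 s or the first 20% of
  points, whichever holds more points (minimum 5). The window exists because
  substrate depletion bends the trace; its exact extent is a free choice and
  is deliberately conservative.
* **REA** — 100 × rate_sample/rate_free, not clipped above 100 (immobilized
  enzymes can out-perform free ones under assay conditions).
* **PI** — computed on the fractional scale, (EE/100)·(REA/100), so it lives
  in [0, 1] whenever REA ≤ 100. No reference value fixes the scale, so the
  bounded choice is used.
* **P_loading** — 100 × encapsulated mass / composite dry mass, computed only
  when a composite mass is supplied (no formula is implied by EE alone).
* **Release** — cumulative percent of the encapsulated mass, clipped to
  [0, 100]; a decreasing cumulative series warns and keeps the running
  maximum.
* **Second-derivative band analysis** — Savitzky–Golay smoothing
  (11-point window, quadratic, configurable) with `deriv=2`; component bands
  are local minima of the second derivative with prominence ≥5% of its
  dynamic range, which makes the result scale-invariant and empty for flat
  spectra. Note an intrinsic limit of the technique, verified analytically:
  for two Gaussian bands 26 nm apart, overlap shifts the second-derivative
  minima away from the true centers by >1 nm once the band width exceeds
  ~8 nm (at width 12 nm the minima sit at 326.5/355.5 nm for true centers
  328/354 nm). Test fixtures use 8 nm bands so they probe the estimator, not
  the overlap artifact.

## Latin hypercube seeding

Plain LHS, hand-rolled: per axis, a random permutation assigns one of n
equal-width strata to each sample, and the coordinate is uniform within its
stratum. Samples then snap to the nearest grid level. Snap collisions redraw
within the *same* strata up to 100 times, then fall back to the nearest
unoccupied grid point — so plans are always distinct and on-grid, and the
pre-snap marginals are exactly stratified (kept on the plan object for
verification). Maximin variants were considered and rejected: plain LHS is
the minimal interpretation, and the space-filling advantage over uniform
sampling (~30% larger mean minimum pairwise distance at n = 15) already
materializes without it. Stratification is over concentrations, not stock
volumes.

## Surrogate models

Five families with fixed, documented hyperparameters (no nested tuning):

| family | estimator | σ(x) |
|---|---|---|
| random_forest | 300 trees | SD of per-tree predictions |
| gradient_boosting | 100 stages | SD over a 30-model bootstrap ensemble |
| gaussian_process | RBF×const + white noise, z-scored X, normalized y | native predictive SD |
| svm | RBF SVR, C = 100, z-scored X | SD over a 30-model bootstrap ensemble |
| neural_network | MLP (32, 32), ≤500 epochs, z-scored X | SD over a 30-model bootstrap ensemble |

σ is zero exactly where all ensemble members agree; μ is clipped below at 0
(EE and PI are non-negative). Selection is by mean out-of-fold MSE over a
10-fold shuffled, seeded partition — retained even at n = 15 (fold sizes
1–2), because the selection must be made under exactly the data budget the
campaign has at that point. Ties break by the fixed precedence
RF > GB > GP > SVM > NN. Selection happens once, on seed data; the chosen
family is then retrained (not cached) every iteration, with per-iteration CV
MSE recorded. Re-selection each round is available by flag.

## Acquisition and batching

Closed-form EI and PoI as given above, with ξ = 0.01. The σ = 0 branches are
conventions: EI = 0 (a point the model is certain about cannot improve in
expectation) and PoI = 1{μ > f′ + ξ}. f′ defaults to the best *model-predicted*
value over tested recipes rather than the best raw observation (the raw best
is inflated by noise); both are exposed in config.

Batch proposal mirrors a generate-then-rank scheme: the 30 highest
acquisition scores over the exhaustively scored untested grid form the
generated set, which is re-ranked by predicted mean and truncated to the 10
sent to the bench. Exact duplicates of tested recipes are excluded;
near-duplicate exclusion is deliberately not applied. Ties break
lexicographically by recipe, making proposals deterministic given (model,
tested set).

## Campaign loop and convergence

Defaults: 15 seeds, batches of 10, ≤9 iterations (105 trials at full budget,
0.59‰ of the default space; the seed set alone is 0.08‰). Every stochastic
stage (LHS, CV partitions, model fits, bootstrap ensembles) draws a child
seed derived from the master seed and a stage label, so campaigns are
bit-reproducible. Failed measurements stay in the audit log with
`status="failed"` and never reach the surrogate; their batch slot is not
refilled.

Early stopping triggers when the relative change of the grid-wide predicted
maximum stays below `convergence_rel_tol` (default 1%) for
`convergence_patience` (default 2) consecutive iterations, with the
selection-stage fit providing the baseline value. Both numbers are invented
— only "convergence of the predicted maximum" is externally specified — and
are config-exposed; `early_stop=False` runs the full budget.

## Interpretation utilities

* **Shapley attribution** — exact interventional Shapley values of the
  fitted surrogate: the value of a coalition S at x is the model's mean
  prediction with x's coordinates on S and background coordinates elsewhere,
  averaged over ≤50 background recipes drawn from the trials. With three
  features all 2³ coalitions are enumerated, so there is no sampling error;
  attributions per point sum to f(x) − E_bg[f]. Reported as mean |value| per
  feature, descending.
* **t-SNE** — scikit-learn, exact gradients, PCA init, perplexity
  min(30, (n−1)/3), fixed seed ⇒ deterministic embeddings.
* **Distribution report** — 5-point bins for EE, 0.05 for PI, extended
  upward only if an observation exceeds the nominal range.

## The synthetic oracle

The oracle emulates the wet lab, not its chemistry. Ground-truth surfaces on
the fractional scale:

* **EE (`saturating_product`)** — lo + (hi − lo) · H(Ca; K=30 mM, p=2) ·
  H(IDC; K=50 mM, p=2) · g(enzyme), with Hill terms H, bounds
  [lo, hi] = [0.2, 0.9], and a mild quadratic enzyme factor g ∈ [0.85, 1]
  centered at 1.08 mg/mL. Monotone non-decreasing in both the metal and
  ligand axes, matching the qualitative attribution finding the loop is
  expected to reproduce.
* **REA (`gaussian_bump`)** — 0.05 + 0.80 · Gaussian centered at
  (26 mM, 60 mM, 0.6 mg/mL) with widths (25, 30, 0.5): the activity optimum
  deliberately occupies a different region than the EE optimum, so
  PI-targeted campaigns must balance the two.
* **`custom_table`** pins arbitrary per-recipe truths for tests.

Measurement adds homoscedastic Gaussian noise of SD 1.7 percentage points
(the magnitude of a typical replicate spread) per replicate (default 3),
truncated to [0, 1]; the reported value is the replicate mean. The noise
model is an assumption — only per-sample spreads are known, not a variance
law. Replicate draws are keyed by (oracle seed, recipe), so measurement
order is irrelevant. With `emit_raw`, the oracle instead emits BCA standards
on a fixed calibration line (0.8 AU per mg/mL, intercept 0.05 AU),
supernatant absorbances implied by each replicate's EE, and linear kinetic
traces whose slopes encode each replicate's REA against a 0.002 AU/s free-
enzyme reference; reducing the bundle through the assay module reproduces the
same trial values (exactly the truth at zero noise).

What the oracle does *not* emulate: mixing-order and pH effects, phase
selection or amorphous failures (tests inject failures explicitly),
heteroscedastic or correlated assay noise, background hydrolysis by the
framework components, and instrument drift. Passing closed-loop tests
therefore demonstrates that the optimizer recovers optima of smooth, bounded
response surfaces under realistic replicate noise — not that it is robust to
every pathology of real bench data.

## Problem sizes used in tests

Simulated campaigns in the test suite and acceptance script run on a
coarsened 17 × 21 × 15 grid (5,355 points; the full 176,851-point grid is
used for enumeration, arithmetic, and pipetting checks). The closed-loop
recovery check runs 20 campaigns at study conditions (noise SD 1.7,
15 + 9 × 10 budget, default early stopping, all five families competing) and
requires the best observation to lie in the top 0.5% of true surface values
in ≥80% of runs; brute-force acquisition comparisons use a 5³ grid.

## Known limitations

* Hyperparameters of the five families are fixed defaults; no claim is made
  that they match any particular prior implementation, and the NN/SVM
  architectures are unspecified externally.
* The 30→10 generate-then-rank batching is a faithful mirror of a scheme
  whose generator is unspecified; on an exhaustively scorable grid the
  generation stage reduces to a top-30 cut.
* PoI-based exploitation is implemented but off by default; when and whether
  to switch from EI is left to the user (`AcquisitionConfig(kind=...)`).
* Per-mille coverage figures quote the default 176,851-point space;
  campaigns on other grids report their own size.
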