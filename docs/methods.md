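# Methods

This note documents the statistical model behind `sigpotency`, the
parameters that matter, the design decisions taken where several choices
were defensible, and what the simulation-based tests do and do not show.

## Normalization model

Raw per-well mRNA counts are normalized strictly per plate against that
plate's neutral-control (NC) wells:

* **Fold change** `FC = 50 · log2(count / median NC count)`, per gene. The
  factor 50 puts a 2-fold change at 50 units; the per-gene NC-median well
  maps exactly to 0.
* **rscore** `R = (FC − median FC_NC) / MAD(FC_NC)`. The MAD is the
  consistency-scaled median absolute deviation (×1.4826), so an rscore
  reads as a number of robust standard deviations from background. The MAD
  is computed on NC *fold changes*, which is the dimensionally consistent
  choice for this ratio. A gene with zero NC MAD carries no information on
  that plate and is dropped with a warning; fewer than 3 NC wells is a
  hard error because the MAD is undefined.
* **HKnorm** subtracts the same well's housekeeper-gene rscore from every
  signature gene, absorbing well-level technical effects; the housekeeper
  column is then removed from the readouts.
* **Probe collapse** keeps, per gene symbol, the probe with the largest
  variance across all wells (ties break to the lexicographically smallest
  probe id); values of retained columns are never modified.
* **Responsive-gene QC**: a gene is considered responsive when, in *every*
  biological replicate, at least 50% of the active-control technical
  replicates show rscore > 3. The rule is applied to AC wells (the wells
  that should respond); the thresholds are parameters.

No between-plate batch correction and no imputation are performed; wells
with missing gene values are rejected at read time because silent
imputation would bias the vector norms all scores are built on.

## Scoring model

Let *p* be a well's per-gene rscore vector over the signature genes, *a*
the active-control signature (per-gene **median** over the plate's AC
wells; the median mirrors the robust NC statistics), and let the NC wells
define a background center (per-gene median) and covariance. The twelve
scores are the standard geometric and statistical summaries listed in the
README. Specific choices:

* **Significance weight** `min(1, mean(|p|)/3)`: 3 rscores is the level
  from which a per-gene signal is considered clearly above background, so
  a signature averaging 3 robust SD gets full weight. The weight is
  computed on the same vector passed to the scorer (housekeeper-corrected
  if HKnorm was applied upstream).
* **Mahalanobis covariance**: the NC sample covariance is replaced by a
  Ledoit-Wolf shrinkage estimate whenever there are no more NC wells than
  genes or the sample covariance is near-singular (the L1000 situation —
  hundreds of genes, a handful of control wells). A small ridge is added
  if the shrunk estimate is still degenerate.
* **Degenerate profiles**: a (near-)zero vector has no direction; the
  direction and correlation scores return 0 with a degeneracy flag rather
  than NaN so that dose-response series remain fittable. Zero directional
  evidence is the scientifically correct reading of a zero effect.
* **Spearman ties** use average ranks.
* **Percent activity** rescales raw scores so the median NC score maps to
  0% and the median AC score to 100%. The AC-similarity distances
  (`euc_AC`, `maha_AC`) are inverted — `100·(d(NC→AC) − score)/d(NC→AC)` —
  so an exact AC match scores 100%. A method whose AC and NC centers
  coincide is uninformative on that plate and raises instead of returning
  unbounded values.
* **Replicates**: each well is scored individually; technical replicates
  are summarized by the median score per concentration before fitting,
  and biological replicates are fitted and evaluated separately.

## Dose-response fitting

Three candidate fits are computed for every percent-activity series:

* **Parametric**: `A(c) = A0 + (Ainf − A0)/(1 + (AC50/c)^hill)` with box
  constraints A0, Ainf ∈ [−50, 500] % of the AC effect, hill ∈ [0.1, 10]
  and AC50 within one log unit of the tested concentration range. The
  hill slope is kept positive and the response direction is carried by
  the sign of (Ainf − A0), so activators and inhibitors share one engine.
  Optimization is bounded trust-region least squares over
  (A0, Ainf, log10 AC50, hill) with five starts (AC50 seeded at the 10th
  to 90th percentile of the tested log range, hill at 1); an optimizer
  failure marks the candidate invalid so selection falls through to the
  constant fit.
* **Nonparametric**: a local quadratic regression with tricube weights
  over the nearest 75% of points in log10 concentration, evaluated on a
  200-point grid. Its potency is the lowest concentration at which the
  smooth crosses 50% activity (log-linear interpolation between grid
  points — with multiple crossings the first is reported). A curve is
  flagged **bell-shaped** when the smoothed maximum lies at an interior
  grid concentration and the smoothed value at the highest tested
  concentration falls below half of that maximum; this captures
  overshoot-and-return shapes without flagging noisy plateaus.
* **Constant**: the mean activity level. Mean > 50% means the compound is
  already fully active below the tested range (potency = lowest tested
  /10, censored `below_range`); otherwise it is inactive in range
  (highest tested ×10, `above_range`). A mean of exactly 50% is treated
  as inactive. The wording of this rule admits two pairings; the
  implemented one is the pharmacologically coherent mapping.

r² of both fit families is computed against the raw (unsmoothed)
activities with the total sum of squares around the data mean. Selection
order: (1) nonparametric r² < 0.5 → data unsuitable, constant fit;
(2) bell shape → nonparametric crossing potency (a bell that never
reaches 50% has no crossing and falls back to the constant assignment);
(3) parametric r² < 0.5 or in-range amplitude |amin − amax| < 30 →
constant; (4) otherwise parametric. Finally, a parametric fit with
Ainf < 50% (strict) is censored one log unit above the highest tested
concentration, on the grounds that so weak a plateau is unlikely to share
the active control's mode of action.

Reported potencies therefore always lie within [lowest/10, highest×10]
and censored potencies sit exactly at a bound, which lets inactive
compounds participate in downstream correlations.

## Simulator

`simulate_plate` draws wells in rscore space: NC wells are isotropic
Gaussian noise; AC wells are `ac_amplitude · u + noise` for a unit AC
direction `u`; compound wells follow
`E(c) · emax_scale · ac_amplitude · d + noise` with `E(c)` a 0→1 hill
curve at the compound's true EC50 and `d` the AC direction rotated by a
per-compound angle inside a seeded random plane (recorded in the output
for reproducibility). Defaults represent the multiplexed-bead setting:
7 genes, AC amplitude 13.2 (≈5 rscores per gene), 24 NC wells, 6 AC
wells, 6 technical replicates, unit rscore noise, and an 8-point 10-fold
dilution grid from 1e-5 to 100 µM. Noise is i.i.d. Gaussian in rscore
space (rscores are robust z-scores by construction); count
overdispersion, bead-chemistry saturation and heavier-tailed noise are
deliberately not modeled.

`simulate_raw_counts` inverts the fold-change/rscore chain so the
normalization code can be tested end to end. Treated and AC wells are
anchored to the sample NC median and MAD of the plate's own NC draws, so
re-normalizing recovers their target rscores exactly; the NC wells
themselves necessarily come back re-standardized (sample median 0,
robust SD 1 per gene), i.e. within the NC-statistics estimation noise of
their targets. A `noise_sd` of 1 is the internally consistent choice when
the simulated scale is called "rscore".

### What the simulation shows — and a calibration caveat

Because direction scores (cosine, correlations) saturate as soon as the
signal clears the noise floor, their activity curves transition at the
concentration of *signal onset*, `E* ≈ 0.577·σ√n / (emax · A)`, not at
the expression midpoint. Two regimes follow analytically and are what the
tests assert:

* **Overshoot benchmark** (emax = 3, strong signature, 20 compounds over
  5 logs): magnitude-based potencies (`vec_norm`,
  `scalar_projection_AC`) sit at the expression midpoint while
  direction-based potencies track onset, ≥1 log unit lower, and the
  AC-similarity (`euc_AC`) activity curves become bell-shaped wherever
  the overshoot peak falls inside the tested window. This reproduces, in
  a controlled setting, the separation between method classes seen on
  real agonist panels, where magnitude-derived EC50s sit more than one
  log unit above the upstream reference readout.
* **Calibrated recovery regime** (emax = 1, signature amplitude at the
  3-rscore significance threshold, small noise): here the significance
  weight ramp carries the dose dependence, and the weighted cosine,
  scalar projection and vector norm all recover the true EC50 within
  2-fold. Plain cosine/correlation still report onset; that is a
  property of the scores, not a defect of the fitter.

Passing these tests shows the machinery behaves as the geometry predicts
under the stated noise model; it does not certify performance on real
plates, where gene-gene noise correlation, plate drift and compound
off-target structure add failure modes the simulator does not emulate.

## Evaluation

Potencies are compared to a reference set per method (and per biological
replicate; a pooled mode averages log potencies first) after harmonizing
compound names (lowercase, whitespace and "-" removed). Metrics:
Pearson and Spearman correlation of log10 potencies and the fraction of
compounds within one log unit of the reference (boundary inclusive).
Censored values — both fitted and reference-side (flat reference curves
censored by their GRInf value against 0.5) — participate at their
assigned bounds, symmetric on both sides of the comparison. Correlations
over fewer than 3 joined compounds are withheld with a diagnostic.

## Problem sizes

The test suite and the acceptance script run entirely on
programmatically generated data: toy plates of 4–130 wells, signature
sizes 1–10 genes (381 for the subsetting check), benchmarks of 20–100
simulated compounds on 8-point grids. These sizes were chosen as the
smallest at which each property is clearly expressed.

## Known limitations

* GCT support is text GCT v1.3 only (no binary GCTX); GCT well metadata
  beyond role/concentration/compound must be supplied by the caller.
* No between-plate normalization: technical replicates on different
  plates are normalized strictly per plate against that plate's own NC
  wells.
* The nonparametric smoother, its r² and the bell criterion are
  documented defaults; any smoother with the same contract would be
  conforming.
* Growth-rate (GR50) fitting of reference viability data is out of
  scope; reference potencies are consumed as given, with only the
  flat-curve censoring rule applied.
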