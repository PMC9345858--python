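# Methods

## Problem and data model

`tcellprox` quantifies the spatial co-localisation of tumour cells and
T cells in tissue-microarray (TMA) cores of solid tumours, and relates it
to patient outcome.  The input is one table per core with a row per
classified cell (centroid x/y in µm; class ∈ {tumour, T cell, other}),
typically exported from a supervised cell classifier such as QuPath's
random-forest object classifier, plus core metadata: patient, sampled
region (tumour centre, CT, or invasive margin, IM) and stained marker
(CD3 or CD8), and a per-patient clinical table with survival times and
covariates.

## The G-cross estimator

For one core, let the tumour cells be the "from" pattern and the T cells
the "to" pattern.  The cross-type nearest-neighbour distance distribution

    G_tumour:T cell(r) = P(nearest T cell within r of a typical tumour cell)

is estimated from the per-tumour-cell distances `d_i` to the nearest T cell
centroid (cell radii are ignored; distances are centroid-to-centroid).
Near the core boundary the true nearest neighbour may lie outside the
observation window, so `d_i` is treated as right-censored at `b_i`, the
distance from cell *i* to the window boundary: the observed pair is
`t_i = min(d_i, b_i)` with event indicator `δ_i = 1{d_i ≤ b_i}`.  The
Kaplan–Meier (KM) edge-corrected estimate is the product-limit CDF

    Ĝ(r) = 1 − ∏_{event times t(j) ≤ r} (1 − e_j / n_j),

with `e_j` events and `n_j` at risk at `t(j)`; ties between events and
censorings at the same distance are resolved events-first (the standard
survival convention; it only matters on sets of measure zero).  The
uncorrected estimator (`RAW`) is the plain ECDF of the `d_i` and is biased
downwards on small windows.  Both are exposed; KM is the default.

A core without T cells gets `Ĝ ≡ 0` under both corrections: the
probability of a tumour cell being co-located with a T cell is zero, and
fixing the value (rather than leaving it undefined) keeps downstream
scoring total.  Curves are right-continuous step functions; evaluation
beyond `r_max` (the largest observed boundary distance) returns the last
value together with a beyond-reliable-range flag, because large
sensitivity radii (500 µm) exceed the reliable range in 1-mm cores yet
must still yield a number.

The observation window defaults to a fixed disc of the nominal core
diameter (1 mm for the primary design; 3 mm cores are supported by
configuration) centred on the cell centroid; convex-hull and buffered-hull
windows are available for irregular tissue.  Whether boundary distances
should use the tissue edge or the core edge is genuinely open for real
data, which is why the window construction is parameterised rather than
fixed.

Nearest neighbours are found with a k-d tree; a dedicated test proves
exact agreement with exhaustive O(n·m) search, and the survival-module
Kaplan–Meier (lifelines) is used as an independent second route through
the identical product-limit arithmetic.

Validation against the analytic null: if T cells form a homogeneous
Poisson process of intensity λ independent of the tumour cells, then
`G(r) = 1 − exp(−λπr²)`.  At λ = 500/mm² and r = 20 µm this is 0.4665;
the replicate-mean KM estimate must sit within ±0.01 of it.  On heavily
censored 200-µm windows the KM estimate is nearly unbiased while the RAW
ECDF is biased low by several points; the edge-correction check therefore
compares the *replicate-averaged* estimates to the closed form (a bias
comparison).  Per-replicate absolute error is dominated by the KM
estimator's larger variance and is not the quantity the correction is
designed to improve.

## Densities and scores

Per core, the density of a class is count / window area (mm²).  Per
patient, the four components — CD3/CT, CD3/IM, CD8/CT, CD8/IM — are the
arithmetic means of the per-core values of the relevant cores.  The same
per-core-then-mean rule is applied to G(r) values as to densities; a
pooled mode (pooling censored distances of all same-component cores into
one product-limit estimate before evaluation) is available behind
`pool_cores=True`, since either reading is defensible for multi-core
patients.

Percentiles are defined as `100 · #{reference ≤ value} / N`, against the
cohort's own component distribution or an external reference (the stored
study-cohort distribution), which makes external-cohort scoring exact and
order-preserving.  The **T cell proximity score** is the mean of the four
G(20 µm) percentiles; the **T cell density score** the mean of the four
density percentiles.  Categories: low [0, 25], intermediate (25, 70],
high (70, 100] — boundary inclusivity read off the interval notation, so
a score of exactly 25 is low and exactly 70 is intermediate.  The default
radius of 20 µm targets T cells close enough for direct cell–cell
interaction; radii {10, 30, 40, 50, 100, 500} µm are supported as a
sensitivity analysis (one extra score column per radius).

Quartile labels (Q1–Q4, low to high) per component use empirical
25/50/75 cut ranks with ties assigned to the lower quartile and
largest-remainder sizing favouring lower quartiles (983 values split
246/246/246/245).  Combined proximity × density subgroups default to
dichotomising each score at low vs {intermediate, high}; the full 3×3
grid is available via `scheme="full"` since the exact published grouping
of such subgroups varies.

Two exact identities pin the scheme down: a tie-free cohort scored
against itself has percentiles {100/N, …, 100}; and with N = 100
perfectly correlated components the categories split exactly
25 / 45 / 30.

## Survival analysis

Follow-up is administratively truncated at 10 years (times clamped,
events cleared).  Kaplan–Meier curves and log-rank tests compare score
categories; Cox proportional-hazards models estimate HRs per category
versus the lowest, with Efron tie handling and Wald 95% CIs on the
log-HR scale (lifelines).  `P_trend` enters the ordinal categories as a
single continuous covariate (0/1/2, or 0–3 for quartiles).  The default
covariate set and reference levels are sex (male), age (<65), operation
period (2000–2005), tumour location (proximal colon), stage (I–II),
grade (low), lymphovascular invasion (no), MMR (proficient), BRAF
(wild-type).  Missing covariate values are assigned to the majority
category with a per-covariate count reported so the imputation is
auditable.  Several exposures may enter one model (reciprocal adjustment
of proximity and density scores).  Subgroup analyses fit per-stratum
models and an interaction p-value from the product of the ordinal
exposure and stratifier codes in a joint model.  Competing risks are not
modelled: cancer-specific analyses censor other-cause deaths.  An
independently computed partial-likelihood fit (R `survival::coxph`,
Efron ties) on a frozen 40-case dataset is baked into the test suite as
a cross-implementation oracle; agreement is required to 1e-4 on the
coefficients.

## Synthetic cohorts

The generator produces data whose truth is known, not an imitation of any
particular cohort:

* **Tumour cells**: Thomas cluster process (Poisson parents, intensity
  κ = 50/mm² simulated on a dilated disc to avoid edge deficits; Poisson
  offspring, mean µ = 12, Gaussian spread σ = 30 µm), giving nest-like
  clusters and ≈ 450–500 tumour cells in a 1-mm core.  A fixed uniform
  tumour count can be requested for analytic null checks.
* **T cells**: total intensity λ_T (default 500/mm² for CD3; CD8 scaled
  by 0.5, invasive-margin cores by 1.5, mirroring the usual density
  ordering).  Each T cell is, with probability ρ, attached to a uniformly
  chosen tumour cell at a half-normal radial offset (σ_a = 10 µm,
  resampled if outside the window), otherwise uniform background.
  ρ = 0 recovers the independent Poisson null exactly.
* **Cohort**: one ρ per patient from a three-group mixture
  {0.1, 0.5, 0.9} with weights (0.25, 0.45, 0.30) chosen to mirror the
  low/intermediate/high prevalence implied by the 25/70 percentile
  thresholds; two cores per marker × region by default.  A balanced mode
  assigns groups round-robin for exactly equal group sizes.
* **Outcomes**: cancer death ~ exponential with hazard
  h0 · exp(β · x), h0 = 0.05/yr, where x is the true group index (or ρ);
  independent other-cause death (0.04/yr), random censoring (0.03/yr) and
  an administrative horizon (15 yr) complete the observation scheme.
  Clinical covariates are drawn independently of outcome with realistic
  marginal frequencies; they exercise model plumbing, not confounding.

Per-core RNG streams are derived from the master seed through a counter
(`SeedSequence([master, counter])`), so cohorts are reproducible under
partial regeneration and all output is bit-identical for a fixed seed.

What the generator does **not** emulate: staining artefacts, necrosis,
classifier error, irregular tissue masks, intra-patient correlation of
covariates with immune infiltration, and 3-D effects.  Passing tests
demonstrate the estimators and scoring arithmetic are correct and that
the pipeline recovers known effects under the generative model — not that
any particular clinical effect size would be reproduced in real tissue.

## Problem sizes and numerical choices

The validation suite uses cohorts of 200–1000 patients (1–2 cores per
component), 200–500 replicate cores for Monte-Carlo calibration, and 500
replicate null cohorts (n = 200) for the trend-test calibration; these
sizes give Monte-Carlo standard errors comfortably below the asserted
tolerances while keeping a full run in the low minutes.  End-to-end
recovery of a hazard trend of log 0.6 per category is asserted within 3
standard errors; the trend-test type-I error at α = 0.05 must land in
[3%, 7%] (±2 binomial SDs at 500 replicates).

Degenerate inputs are handled explicitly: zero-area windows, hulls of
collinear points and negative radii raise typed errors; constant
component distributions yield all-Q1 quartiles with a warning; cores
with no T cells score G = 0; strata without events are skipped with a
warning; non-converging Cox fits raise a fit error (the pipeline logs
and skips such models on degenerate mini-cohorts rather than aborting a
run).

## Known limitations

* The KM G estimator assumes censoring at the window boundary is
  independent of the distance structure; strongly inhomogeneous patterns
  violate this, as for any product-limit edge correction.
* Percentile scores are cohort-relative; scoring a new cohort requires
  either the stored reference or acceptance of self-referencing.
* The interaction test codes multi-level stratifiers ordinally with one
  product term; for nominal stratifiers with > 2 levels this is a trend
  in the stratifier, not a saturated interaction.
* Proportional-hazards diagnostics (Schoenfeld residuals) are not
  included.
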