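# Methods

This note documents the statistical procedures, their assumptions, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## Tau accumulation rates

Each region is fitted independently with the linear mixed-effects model
`SUVR ~ time` with correlated random intercept and slope per subject
(unstructured covariance, REML, L-BFGS, max 200 iterations). A subject's
reported rate is the BLUP: fixed slope plus the subject's predicted random
slope. Subjects contribute 2–4 scans over up to four years; subjects with a
single scan are dropped from that region with a warning, never imputed.

*Fallbacks.* When a fit degenerates (non-finite estimates, random-effect
variance below 1e-10, or residual variance below 1e-10) the region falls
back to per-subject ordinary least-squares slopes and is flagged. When every
subject's trajectory is an exact line (and at least one subject has ≥3
scans, so exactness is detectable), per-subject least squares is returned
directly — it is the maximum-likelihood answer and avoids asking the
optimizer to estimate a zero variance. The optimizer's own convergence flag
is recorded but not used to discard fits: on these models it is routinely
pessimistic while the variance components and BLUPs are stable.

*BLUP under a global null.* If the true between-subject slope variance at a
region is zero, the mixed model correctly estimates τ² ≈ 0 and shrinks every
subject onto the shared fixed-effect slope map. Every subject's spreading
statistic then equals the correlation between that one map and the distance
map — a single O(1/√R) random quantity that does not average out over
subjects. Null-calibration checks of the spreading statistic therefore use
per-subject least-squares slopes, whose errors are independent across
subjects; the mixed-model path is unchanged for data with real slope
heterogeneity.

## Epicentre detection

The two-component univariate Gaussian mixture is fitted per region on the
pooled baseline SUVR (all subjects, one fit per region) by EM: means
initialized at the 10th/90th percentiles, shared initial SD, equal weights;
10 jittered restarts keep the best log-likelihood; tolerance 1e-8; variance
floor 1e-6 prevents component collapse; the log-likelihood is asserted
non-decreasing at every step. Components are ordered by mean.

A parcel is excluded from epicentre selection when the high mode is not
separable: ΔBIC = BIC(1-component) − BIC(2-component) < 10, or the component
means are closer than 0.5 pooled SD. Both thresholds are arguments. This is
a purely statistical operationalization of "low-tau parcels where one and two
components fit almost identically"; no anatomical lookup is used.

Scoring: posterior probability of the high component (log-space, numerically
exact against the direct density ratio), multiplied by the raw SUVR. Ties in
the top-k selection break by higher raw SUVR, then lower region index.
Amyloid positivity uses strict greater-than comparisons at the per-tracer
cutoffs (AV45 1.11, FBB 1.08, PiB DVR 1.2).

## Connectivity processing

Framewise displacement is the sum of absolute frame-to-frame changes in the
six rigid-body parameters, rotations converted to arc length on a 50 mm
sphere (configurable radius). Frames with FD > 1 mm are censored together
with one frame before and one after; subjects with > 30% censored volumes are
flagged excluded (an all-censored run is an exclusion, not an exception).
Cleaning order per region: linear detrend → regression of detrended motion
and nuisance columns → 2nd-order Butterworth band-pass (0.01–0.08 Hz)
applied forward-backward on each contiguous surviving segment, dropping
segments shorter than 24 frames (too short for stable filtering).

Connectivity is the Fisher-z transform of Pearson correlations, with r
clipped to ±(1 − 1e-6); a partial-correlation variant uses the
ridge-regularized inverse covariance (ridge = 0.1 × mean diagonal). The
normative template keeps, per subject, the round(0.30 × P) strongest
*positive* off-diagonal edges (P = number of unordered pairs; negative edges
are zeroed first because path lengths require nonnegative weights) and
averages element-wise. The averaged template is used as-is for distance
conversion, without re-thresholding. Distances are all-pairs Dijkstra with
edge length 1/weight; a disconnected template raises an error naming the
components. Subject-level FC used for the FC-to-epicentres metric is the
unthresholded Fisher-z matrix.

## Spreading statistics

Distance to an epicentre set is the arithmetic mean over its members
(minimum available as an option). The per-subject β is the Pearson
correlation between regional rates and distances across non-epicentre,
non-excluded regions — covariates are subject-constant and cannot enter this
within-subject regression; adjustment happens in the group-level and
subject-level models. The group β map fits, per region, rate on distance
(both standardized across subjects) plus standardized covariates (age, sex,
MMSE, education). Association models standardize continuous variables so
coefficients are standardized βs, include main effects plus a product term
when a binary moderator is supplied, and report two-sided inference without
multiplicity correction.

## Mediation

The mediator model is a logistic regression (Newton-Raphson; a quasi-separated
fit — non-convergence or |linear predictor| > 30 — is refit with a small L2
penalty and a warning). The outcome model is linear with no
exposure–mediator interaction, so `total = ACME + ADE` holds exactly.
The treatment is standardized and the default contrast (0, 1) is a 1-SD
increase. Uncertainty comes from subject-level bootstrap resampling (default
1000 draws; resamples lacking both mediator levels are redrawn), percentile
95% CIs and two-sided add-one-corrected p-values. When the mediator is
continuous the mediator model is linear and the ACME reduces to the product
of coefficients. When APOE status is the mediator, Aβ status enters as a
covariate, and vice versa. With a continuous treatment the potential-outcomes
contrast is a modelling choice; treating genotype as a mediator is a
statistical, not a causal, statement.

At n = 500 the ACME estimate in the closed-form benchmark (no covariates,
α₀ = −0.5, α₁ = 1, θ_M = 0.3; true ACME ≈ 0.0735) carries roughly 8%
irreducible sampling noise from the Bernoulli mediator, so accuracy checks
compare the estimate averaged over replicate cohorts with the Monte-Carlo
oracle.

## Influence maps

Within each subject, FC-to-epicentres is regressed on the group β map across
that subject's eligible regions; residuals are internally studentized
(residual / (s·√(1−h))), with a relative threshold that returns exact zeros
for numerically perfect fits. Each region is scored by the two-sample
Wilcoxon rank-sum of its residuals (across subjects) against the pooled
residuals of all other regions, standardized with tie correction (a
one-sample signed-rank variant is available). The null repeats the entire
procedure with the β map's region labels shuffled — the same shuffle across
subjects within an iteration, preserving subject structure while breaking
map alignment.

Significance defaults to the exact two-sided permutation p-value with
add-one correction. The normal approximation to the permutation z is
available as an option but is *not* the default: at cohort scale the
rank-sum permutation null is visibly non-normal (pooled null z SD ≈ 0.85 at
20 subjects × 25 regions and ≈ 1.13 at 50 × 100), so normal-p thresholding
over-calls (~10% of null regions at α = 0.05) whereas the exact permutation
rank is calibrated (the observed statistic's rank within its own null is
uniform). z-scores are still reported as the effect-size map.

The statistic flags regions whose FC is *specifically explained by the
aligned β map* — not regions with large β — and it saturates when per-region
offsets dwarf within-region variability (all of a region's residuals then
occupy the extreme ranks under every permutation). Its informative regime is
offsets comparable to residual spread.

## Synthetic cohort generator

The generator plants exactly the structure the analysis assumes, at
magnitudes chosen once to be detectable at the package's reference scale
(150 subjects, 50 regions):

* **Connectome**: spatially embedded modular graph — modules on a 60 mm
  ring, regions scattered 8 mm around module centres, edge weight
  exp(−distance/40 mm) damped ×0.6 between modules, ±15% multiplicative
  noise. Spatial embedding matters: with block-constant weights,
  shortest-path distances to the epicentre module are nearly constant across
  regions and the planted distance-rate gradient carries almost no spatial
  contrast.
* **Epicentres**: one module plays the medial-temporal role; each subject's
  set is the archetype (the k regions nearest that module) with each member
  swapped out with probability 0.2 for another pool member, so individual
  and group epicentre logic are both exercised.
* **Rates**: rate(s, r) = a_s · exp(−0.15 · d̄(r, E_s)) + N(0, 0.002), with
  coupling a_s = 0.005 + 0.02·APOE4 + 0.03·Aβ + N(0, 0.008) SUVR/year
  (floored at 0). Peak planted rates are ≈ 0.01–0.035 SUVR/year, in the
  range reported for amyloid-positive elderly cohorts. The coupling spread
  spans near-zero to strong spreading so that β varies over its informative
  range instead of saturating at −1.
* **Baseline SUVR**: low mode 1.2 ± 0.05, high mode +0.6 at the subject's
  epicentres; any region has a 15% chance of non-specific elevated binding
  at 0.7 × the epicentre delta, which makes every parcel's pooled baseline
  bimodal (mirroring the mixture assumption) and gives the selection rule
  genuine competitors.
* **Scans**: 2–4 visits at nominal years 0–3, jitter ±0.25 y, measurement
  noise 0.005 SUVR (optimistic but within parcel-level test-retest).
* **FC**: subject matrix = template + symmetric N(0, 0.05) noise, with
  epicentre↔non-epicentre cells depressed by gain × a_s (gain 1 Fisher-z per
  SUVR/year) — tau-dependent disconnection.
* **Mediation chain**: APOE drawn first (prevalence 0.40), Aβ from a
  logistic in APOE (intercept −0.5, coefficient 1.5, overall positivity
  ≈ 0.53), coupling from both; covariates match an elderly
  amyloid/tau-imaging sample (age 68.8 ± 6.2, education 16.3 ± 2.5,
  MMSE ≈ 28.5, 57% female).
* Optionally, parcel time-series whose correlation approximates tanh(z) via
  an eigen-clipped Cholesky factor, plus random-walk motion with 2% spike
  frames and two nuisance regressors, so the QC stage is exercisable.

What it does **not** emulate: spatial autocorrelation of noise, haemodynamics,
scanner or site effects, off-target binding topography, atrophy,
non-linear trajectories, and real connectome topology beyond modularity plus
spatial embedding. Passing recovery tests therefore shows the estimators are
correct and well-calibrated under the model's own assumptions — not that the
assumptions hold in real data.

A separate triplet generator plants (X, M binary, Y) mediation structure
with a known ACME; its brute-force potential-outcomes Monte-Carlo oracle
(n ≥ 10⁴ draws, SE reported) is the reference all mediation accuracy checks
compare against.

## Numerical and reproducibility choices

Degenerate inputs are handled without exceptions where the quantity is still
defined: all-equal baseline → parcel excluded; zero-variance β inputs →
flagged undefined; all-tied residuals → statistic at its expectation.
Matrices are validated symmetric to 1e-8 with zero diagonals; CSV readers
parse floats in round-trip mode so a written bundle reloads bit-identically.
Every stochastic stage derives its seed from the pipeline master seed via
`SeedSequence` spawning; the manifest (config echo, per-stage seeds, content
hashes) suffices to reproduce a bundle byte for byte.

Reference problem sizes used by the test-suite and the acceptance script —
150 subjects × 50 regions for recovery, 200 replicates for CI coverage,
40 null datasets × 1000 permutations for false-positive calibration — were
chosen as the smallest sizes at which the planted effects and the calibration
bands are statistically resolvable.

## Known limitations

* The distance conversion (1/weight Dijkstra) is one reading of
  "shorter path lengths mean better connectedness"; alternatives are
  pluggable (`euclidean` with region coordinates is built in).
* Whether the averaged template should be re-thresholded before distance
  conversion is undetermined; it is used as-is.
* The group β map fed to influence maps is the full-sample map; stratified
  analyses (by APOE/Aβ) are the caller's responsibility.
* The rank-sum's comparison group ("region versus all other regions pooled")
  is one of two defensible readings; the one-sample signed-rank alternative
  is provided behind a switch.
* No spatial-autocorrelation-preserving nulls (spin tests) and no
  cluster-extent correction.
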