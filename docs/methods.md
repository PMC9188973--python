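# Methods

`specverse` implements a multiverse (specification-curve) analysis of
task-evoked amygdala reactivity and amygdala–mPFC functional connectivity
in an accelerated longitudinal cohort, together with the synthetic-data
generator that makes every stage testable against known ground truth. This
note documents the models, the generative assumptions, the numerical
choices, and the limits of what the synthetic studies can show.

## The scientific setting

Developmental task-fMRI studies ask how the amygdala's response to emotional
faces, and its coupling with medial prefrontal cortex (mPFC), change from
early childhood to early adulthood. Findings in this literature conflict,
and one suspected driver is analytic flexibility: choices of preprocessing
software, nuisance regression, HRF shape, ROI definition, connectivity
method, and group-model structure can each move the estimate. A multiverse
analysis runs all reasonable combinations of such choices ("forks"), ranks
the resulting estimates into a specification curve, and summarizes evidence
continuously — the proportion of specifications whose estimate shares the
median's sign, and the proportion whose 95% interval excludes zero —
instead of privileging one pipeline.

Real data for the emulated design (an event-related fear/neutral face task
in 4–22-year-olds, 1–3 scans per participant at ~18-month intervals) cannot
be redistributed, so every pipeline stage here runs on simulated ROI
timeseries whose generative parameters are known, making parameter recovery
the test of correctness.

## Synthetic cohort and BOLD model

The cohort generator draws starting ages approximately uniform over 4–22
years and assigns 1–3 scans per participant at 1.5-year intervals (default
composition 40/31/27 participants with 1/2/3 scans: 98 participants, 183
scans). Wave 3 switches scanner label, emulating a site change that group
models may absorb as a covariate.

Each run has 48 face events (24 fear, 24 neutral, 350 ms) in 130 volumes at
TR = 2 s. Real designs of this kind are jitter-optimized with a genetic
algorithm; we draw inter-trial intervals from a truncated exponential on
[3, 10] s targeting the reported median of 4.93 s and resample until the
train fits the run. (A uniform draw on [3, 10] s has mean 6.5 s and cannot
fit 48 trials into 260 s; the median-targeting sampler is therefore the
default, not an option.)

Trial-level neural amplitude for condition *c* at trial *i* is

    a_i = baseline_c + age_slope_c (age − 12) + [h0 + h1 (age − 12)] (i − 1)
          + participant offset + sd (√ρ_c z_i + √(1−ρ_c) e_i)

with a shared standard-normal z_i inducing trial-amplitude correlation ρ_c
between the amygdala seed and the mPFC targets. Defaults: fear baseline 1.0
(neutral 0.8) in arbitrary BOLD units; age slopes −0.05/yr (fear) and
−0.03/yr (neutral); habituation h0 = −0.02 per trial with interaction
h1 = +0.002 per trial per year (steeper habituation at younger ages);
participant SD 0.2 (the stable trait that gives measures nonzero
test–retest reliability); trial SD 0.25; coupling ρ = 0.35 (fear) / 0.15
(neutral). These encode the qualitative pattern of the emulated study — a
detectable negative reactivity–age slope and an FC age slope near zero —
at magnitudes in the range of published task-fMRI effects.

BOLD is the convolution of the amplitude-weighted event train with a
double-gamma HRF (difference of two gamma densities; response peak 6 s,
undershoot peak 16 s, undershoot ratio 1/6, unit-peak normalized so betas
are on the amplitude scale), sampled at volume times, plus: AR(1) noise
(φ = 0.3, SD 0.5), polynomial drift, a low-frequency global component added
to every ROI, and motion artifacts proportional to framewise displacement.
Realignment parameters are heavy-tailed (t₄) random walks whose step scale
decreases with age, so mean FD falls from ~0.3 mm at age 4 to ~0.1 mm at
age 22 and occasionally spikes past the 0.9 mm censoring threshold. FD is
the sum of absolute backward differences of the six parameters with
rotations converted to mm on a 50 mm radius. Left/right amygdala and the
four mPFC targets (three spheres plus a large vmPFC mask) are distinct
columns sharing the relevant amplitude series plus ROI-specific noise
(SD 0.15), which is how ROI-definition forks are emulated without any image
registration. WM/CSF columns carry drift/global/motion but no task signal.

What the generator does **not** emulate: volumetric data and registration,
spatial smoothing, slice timing, physiological noise structure
(cardiac/respiratory), non-Gaussian BOLD nonlinearity, or genuine
preprocessing-software differences. Forks labeled "preprocessing software"
and "GLM software" are carried through the grids as labels so enumeration
and curve metadata match the emulated design, but they do not change the
computation on ROI timeseries. Passing tests therefore show that the
*statistical* pipeline recovers what it should under this generative
family; they cannot certify behavior under artifacts the generator omits.

## Scan-level estimation

The condition-level GLM includes fear and neutral regressors (convolved
with the chosen HRF), their temporal derivatives (backward differences of
the convolved regressors, a documented substitute for basis-function
derivatives), an intercept, drift columns, and a nuisance set. Drift
removal is either a discrete-cosine basis with floor(2·T·0.01 Hz) columns
(= 5 for the default run) — a deterministic regressor substitute for a
running-line high-pass filter — or orthogonalized linear+quadratic trends.
Nuisance sets: the 6 realignment parameters; the 24-regressor expansion
(parameters, derivatives, squares of those 12); or 18 + WM + CSF tissue
signals. Volumes with FD > 0.9 mm get weight 0; scans with more than 40
such volumes are flagged excluded. Estimation is weighted least squares
with optional single-lag Cochrane–Orcutt prewhitening (estimate lag-1
residual autocorrelation, quasi-difference, refit) — a global AR(1) stand-in
for voxelwise prewhitening. Contrasts: fear > baseline, neutral > baseline,
and their difference, reported as beta or t.

One measured caveat: when amplitudes carry a monotone within-run trend
(habituation), the high-pass basis absorbs part of it and the condition
beta is attenuated by a few percent relative to the arithmetic mean
amplitude. This is expected filter behavior, so the unbiasedness check
plants trend-free amplitudes, and trend recovery is validated through the
trial-dynamics pathway instead.

Single-trial betas use least-squares-separate (LSS): one GLM per trial with
the target trial's regressor, a single regressor for the other 47 trials,
and the same nuisance/drift/censoring structure. With trials spaced beyond
the 32 s HRF support and a pure trial-regressor design, LSS equals the
all-trials-separate (LSA) solution exactly; this is the oracle test.
Trial-wise global-signal correction is post hoc distribution centering:
subtract each trial's across-ROI mean beta. Note that centering over a
small P-region panel attenuates a true inter-regional correlation ρ by
about (1 + 2ρ)/P while removing the shared artifact; recovery-to-ρ holds
for whole-brain-like panels, and the packaged 7-ROI panel trades a small
attenuation for artifact removal. Within-scan dynamics are summarized per
condition as the Spearman correlation of beta with trial number (ties
mid-ranked; constant series → 0 with a degeneracy flag) and as first-half
(trials 1–12) vs second-half (13–24) means.

## Connectivity

gPPI regresses a target ROI on: per-condition convolved task regressors
(psych), the mean-removed seed timecourse (physio), and one interaction
(PPI) term per condition, plus drift and nuisance. Without deconvolution
the PPI term is physio × convolved-task; with deconvolution the seed is
inverted to a neural-scale series by ridge regression against the HRF
convolution operator on the volume grid (λ default 1.0, scaled by the mean
diagonal of HᵀH), multiplied by the TR-sampled task indicator, and
re-convolved. The exact reference deconvolution is known to be unstable to
small implementation tweaks, so a deterministic ridge inverse is used and λ
is exposed as an optional fork. Main-analysis deconvolution pipelines do
not center the task regressor; centering is a separate fork that alters
only the interaction term. Contrasts are taken on the PPI betas; the physio
beta is reported as task-independent FC.

BSC correlates the per-trial beta series of seed and target within a
condition (≥ 4 paired non-missing trials), Fisher-z transforms, and clamps
|r| ≥ 1 − 10⁻⁶ with a flag. Cross-method concordance is the Spearman
correlation matrix of scan-level estimates across method/fork columns.

## Group-level models

Any scan-level measure is modeled as

    measure ~ f(age) + mean_FD [+ block + scanner] + (1 [+ age] | participant)

with f(age) linear, quadratic, or inverse (1/age on raw years); age is
centered at 12 years (the study does not state a centering; 12 y is near
the cohort mean). Age terms are reported per year — at this scale no
further rescaling is needed for numerical stability. The within/between
parametrization replaces age with the participant's mean age (between) and
the deviation from it (within); the within term is flagged inestimable in
purely cross-sectional tables. The ±3 SD outlier rule is applied per
measure over all scan-level estimates before modeling, with a zero-SD
guard and an exclusion log.

Two estimation paths:

* **fast_freq** — REML via statsmodels MixedLM with Wald 95% intervals
  (optimizer fallback chain lbfgs → bfgs → powell, since boundary fits can
  throw singular-matrix errors mid-optimization). The robust variant
  maximizes the marginal likelihood of a student-t(ν = 4) observation model
  with normal random intercepts (Gauss–Hermite quadrature, 21 nodes) and
  takes Wald intervals from a finite-difference Hessian. Robust fits use
  random intercepts only.
* **bayes_mcmc** — affine-invariant ensemble MCMC (emcee) on the marginal
  posterior: random effects integrated out analytically (Gaussian case,
  Woodbury identity per participant; supports a correlated random age
  slope) or by quadrature (t likelihood). Priors are weakly informative
  student-t(3, 0, 10) on standardized fixed effects and half-t(3, 0, 2.5)
  on SDs; outcome and continuous predictors are standardized internally and
  draws mapped back. Defaults (700 steps, 250 burn-in, ≥ 16 walkers) retain
  several thousand draws; convergence is flagged via split-R̂ across
  walkers (< 1.05), never silently.

The evidence summary across a grid is deliberately not a multiple-testing
procedure: specification curves report continuous proportions, and the
decision-point meta-regression (OLS of point estimates on indicator-coded
decision levels, reference level = first sorted level, with an aliasing
check for curated grids) quantifies each choice's conditional effect.

Trial-dynamics models: (1) scan-level Spearman slopes regressed on age;
(2) half means with an age × half interaction and scan-level pairing
(variance component for scans nested in participants); (3) trial-level
betas with a trial × age interaction. With the default generative
interaction (habituation steeper at younger ages) the age coefficient on
slopes is positive — slopes relax toward zero with age.

Anxiety models standardize the outcome (parent-report separation-anxiety
raw or t-scores; raw scores decrease with age by construction, t-scores
are age-standardized) and regress on the standardized brain measure, age,
and mean FD with participant random intercepts; scans without parent
reports (ages ≥ 18) are dropped. Missing SCARED items are imputed by
k-nearest-neighbor (k = 5): Euclidean distance on standardized mutually
observed items, ties broken by row order, and the neighbor pool widened
with a flag when fewer than k candidates exist.

## Specification grids

The packaged default grids reproduce the emulated study's printed totals:
2,808 reactivity specifications (156 participant-level × 18 group-level),
288 gPPI (4 × 4 mPFC ROIs × 18), 168 BSC (3 × 4 × 2 × 7), 42 trial-dynamics
(3 × 2 × 7), and anxiety families of 18/90/18/12. The printed totals are
not full cross-products of the published decision table, and the exact
memberships are not recoverable; the packaged curated lists (13
preprocessing/GLM cores; 18 and 7 group-model lists built from covariate,
outlier, quadratic, and random-slope choices) are this package's
reconstruction of those counts, documented as such. Fork ids are content
hashes of the decision mapping, which makes sweeps resumable; per-spec
failures are logged without aborting, and a sweep errors out only past a
20% failure fraction.

## Reliability

Test–retest ICC of a scan-level measure comes from the same multilevel
model used for its group analysis (mean-FD covariate included by default,
removable). The fast path is σ²_between/(σ²_between + σ²_within) from a
random-intercept REML fit with a participant-bootstrap percentile interval
(seeded). The posterior-predictive path simulates, per posterior draw, the
measure conditional on random effects and marginally, and reports
1 − var(conditional)/var(marginal); finite simulated vectors make negative
draws possible (the real method shares this property). Conditioning is at
observed covariate values. Bands: poor < 0.4, fair [0.4, 0.6),
good [0.6, 0.75), excellent ≥ 0.75; negative values are poor.

## Calibration studies and problem sizes

Group-model calibration (coverage of a planted −0.05/yr slope, sign
recovery of the habituation × age interaction, null calibration) runs at
the amplitude level: scan measures are drawn from the generative amplitude
model plus estimation noise, skipping the BOLD→GLM stage that is validated
separately by the exact-oracle and unbiasedness checks. This keeps a
100-cohort study in seconds-per-cohort territory. Null calibration pools
reduced-grid (24-spec, random-intercept) estimates across independent
zero-effect cohorts: within a single cohort the forks are strongly
correlated, so the per-cohort same-sign proportion is near 0 or 1 even
under the null, while the pooled proportion is ~0.5 and the mean
excludes-zero rate ~0.05. The acceptance script uses 40–60 replications
per study; the test suite uses the same sizes.

## Known limitations

* Software-labeled forks (FSL/C-PAC/AFNI) are metadata-only; the package
  starts at ROI timeseries by design.
* The ridge deconvolution is a deterministic substitute, not a replica, of
  the reference algorithm — which is itself reported to be unstable.
* Global AR(1) prewhitening, DCT high-pass, and backward-difference
  derivatives are documented substitutes for the corresponding voxelwise
  or filter-based operations.
* Robust Bayesian/ML fits support random intercepts only.
* Curated grid memberships are reconstructions; only their counts are
  anchored.
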