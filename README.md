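# specverse

Multiverse (specification-curve) analysis of task-fMRI ROI measures:
age-related change in task-evoked amygdala reactivity and amygdala–mPFC
functional connectivity in an accelerated longitudinal cohort, with every
stage driven by a synthetic-data generator whose ground truth is known.

## Who this is for

Developmental cognitive-neuroscience and neuroimaging-methods researchers
who want to (a) quantify how robust an age-related brain effect is to
analytic choices, and (b) test a full ROI-level pipeline — GLMs,
single-trial estimation, connectivity, multilevel growth models,
reliability — against simulations with planted effects, without access to
any real MRI data.

## What it computes

Starting from per-scan ROI BOLD timeseries, event tables, and confounds
(simulated here, but the same plain-text formats any ROI-extraction step
produces), the pipeline estimates for each scan:

* **Reactivity** — condition-vs-baseline GLM contrasts (fear > baseline,
  neutral > baseline, fear > neutral) under forks for HRF shape, nuisance
  set (6 / 24 motion regressors / 18+WM+CSF), drift removal (0.01 Hz DCT
  high-pass vs quadratic), FD > 0.9 mm censoring, prewhitening, and
  beta-vs-t output.
* **Single-trial dynamics** — 48 least-squares-separate (LSS) betas per
  scan; Spearman slope of beta across trials and first/second-half means,
  with optional global-signal (distribution-centering) correction.
* **Connectivity** — gPPI (with and without ridge deconvolution of the
  seed, with an optional task-centering fork) and Fisher-z beta-series
  correlation (BSC).

Scan-level measures feed multilevel growth models

    measure ~ f(age) + mean_FD [+ block + scanner] + (1 [+ age] | participant)

with linear / quadratic / inverse-age forms, a within/between-participant
age decomposition, ±3 SD outlier rules, robust (student-t) variants, and
either fast REML or ensemble-MCMC Bayesian estimation with student-t(3, 0,
10) priors. A multiverse engine enumerates the packaged specification grids
(2,808 reactivity / 288 gPPI / 168 BSC / 42 trial-dynamics forks), runs all
forks with failure isolation, ranks estimates into specification curves
with continuous evidence summaries (proportion of estimates sharing the
median's sign; proportion of 95% intervals excluding zero), and regresses
estimates on decision indicators to quantify each choice's conditional
effect. Test–retest reliability of any scan-level measure is a
variance-decomposition ICC (posterior-predictive or fast variance-
components path; negative values possible) with poor/fair/good/excellent
bands.

See `docs/methods.md` for the generative model, priors, numerical choices,
and limitations.

## Worked example

```python
import specverse as sv
from specverse.aims import run_aim
from specverse.simulate import simulate_study

# a full synthetic study: 98 participants, 183 scans, ages 4-22
study = simulate_study(sv.CohortConfig(), sv.GenerativeParams(), seed=1)

grid = {
    "factors": {
        "amygdala_roi": ["amyg_bilateral", "amyg_left", "amyg_right"],
        "estimate_type": ["beta", "t"],
        "hrf": ["double_gamma", "single_gamma"],
        "covariates": ["mean_fd", "mean_fd+scanner"],
    }
}
res = run_aim("reactivity", study, grid=grid, seed=1)
print(f"{len(res.estimates)} specifications, "
      f"median age slope {res.curve.median:.3f}, "
      f"same-sign proportion {res.curve.prop_same_sign:.2f}")
```

Output:

```
24 specifications, median age slope -0.030, same-sign proportion 0.92
```

92% of the forks share the median's negative sign: the planted decline of
amygdala reactivity with age survives nearly every analytic variant in
this grid. The median of −0.030/yr sits where the generative model puts
the marginal trend (a −0.05/yr fear-amplitude slope partly offset by the
habituation × age interaction, which contributes about +0.02/yr to the
run-average amplitude); the beta-scale and t-scale forks are mixed in the
curve. Per-fork estimates and intervals are in `res.estimates`, and
`res.effects` gives the conditional effect of each decision point.

Reliability of a scan-level measure:

```python
from specverse.simulate import simulate_scan_measures
from specverse.reliability import icc_variance_components

m = simulate_scan_measures(seed=1)
est = icc_variance_components(m, "reactivity", n_boot=200)
print(f"ICC = {est.icc:.2f} [{est.lower:.2f}, {est.upper:.2f}] "
      f"({est.reliability_band})")
```

```
ICC = 0.28 [0.01, 0.51] (poor)
```

A command-line interface wraps the same calls:

```bash
specverse simulate --seed 1 --out study/
specverse run --aim reactivity --seed 1 --out results/ --n-participants 12
specverse curve --in results/estimates.csv --plot curve.png
specverse icc --measures measures.csv --measure reactivity
```

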