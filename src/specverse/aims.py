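"""End-to-end execution of one analysis family over a simulated study.

``run_aim`` chains scan-level estimation under the participant-level forks
(GLM contrasts, LSS trial betas, gPPI, BSC) with group-level multilevel
models under the group-level forks, then builds the specification curve
and decision-effect meta-regression. Scan-level work is cached per
distinct participant-level pipeline so the group-model sweep dominates.

Forks that label upstream image-preprocessing software (FSL vs C-PAC, FSL
vs AFNI GLM) are carried as labels only: image-level preprocessing is out
of scope here, so those forks do not alter the computation on ROI
timeseries (the grids keep them so enumeration counts and curve metadata
match the emulated study's decision table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AnxietyParams, generate_anxiety_scores
from .connectivity import bsc, build_gppi_design, fit_gppi
from .glm import expand_motion_regressors, fit_scan_contrasts
from .group_models import AgeModelSpec, fit_age_model, fit_brain_anxiety_model
from .multiverse import (
    SpecCurve,
    Specification,
    build_spec_curve,
    decision_effects,
    default_grid,
    enumerate_specs,
    run_multiverse,
)
from .simulate import SEED_ROIS, TARGET_ROIS, SimulatedStudy
from .single_trial import apply_global_signal_centering, fit_lss, slopes_table

AIMS = ("reactivity", "trial_dynamics", "gppi", "bsc", "anxiety")
_N_PRIOR_PARTICIPANTS = 42  # wave-1 scans treated as previously analyzed


@dataclass
class AimResult:
    aim: str
    estimates: pd.DataFrame = field(repr=False)
    failures: list = field(default_factory=list)
    curve: SpecCurve | None = None
    effects: pd.DataFrame | None = None


def _group_spec(d: dict[str, str]) -> AgeModelSpec:
    return AgeModelSpec(
        age_form="quadratic" if d.get("quadratic", "no") == "yes" else "linear",
        covariates=d.get("covariates", "mean_fd"),
        random_slopes=d.get("random_slopes", "yes") == "yes",
        robust=d.get("outlier", "") == "exclude_3sd_plus_robust",
        outlier_rule=d.get("outlier", "exclude_3sd"),
        estimation=d.get("estimation", "fast_freq"),
    )


def _prior_scan_ids(meta: pd.DataFrame) -> set[str]:
    wave1 = meta[meta["wave"] == 1].sort_values("participant_id")
    return set(wave1["scan_id"].head(_N_PRIOR_PARTICIPANTS))


def _fit_group(measures: pd.DataFrame, outcome: str, d: dict, seed: int):
    spec = _group_spec(d)
    ests = fit_age_model(measures, outcome, spec, seed=seed)
    return ests[0]  # linear age term (or first age term)


# ---------------------------------------------------------------------------
# scan-level caches


def _reactivity_scan_table(
    study: SimulatedStudy, cores: list[tuple[str, str, str]]
) -> pd.DataFrame:
    frames = []
    for hrf_kind, nuisance, drift in cores:
        for scan in study.scans:
            tab = fit_scan_contrasts(
                scan, rois=SEED_ROIS, hrf_kind=hrf_kind,
                nuisance_set=nuisance, drift=drift,
            )
            tab["hrf"] = hrf_kind
            tab["nuisance"] = nuisance
            tab["drift"] = drift
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def _gppi_scan_table(study: SimulatedStudy, deconv_levels: list[str]) -> pd.DataFrame:
    rows = []
    for scan in study.scans:
        nuis = expand_motion_regressors(scan.realignment_params, "24")
        for level in deconv_levels:
            gd = build_gppi_design(
                scan.roi_timeseries["amyg_bilateral"],
                scan.design,
                deconvolve_seed=(level == "yes"),
                nuisance=nuis,
                fd_series=scan.fd_series,
            )
            for target in TARGET_ROIS:
                for est in fit_gppi(scan.roi_timeseries[target], gd):
                    rows.append(
                        {
                            "scan_id": scan.scan_id,
                            "deconvolution": level,
                            "mpfc_roi": target,
                            "contrast": est.contrast,
                            "beta": est.estimate,
                            "t": est.estimate / est.se
                            if est.se and np.isfinite(est.se) and est.se > 0
                            else np.nan,
                        }
                    )
    return pd.DataFrame(rows)


def _lss_tables(study: SimulatedStudy) -> dict[str, pd.DataFrame]:
    raw = pd.concat([fit_lss(scan) for scan in study.scans], ignore_index=True)
    return {"no": raw, "yes": apply_global_signal_centering(raw)}


def _bsc_scan_table(
    lss: dict[str, pd.DataFrame], condition: str = "fear"
) -> pd.DataFrame:
    rows = []
    for gss, table in lss.items():
        for scan_id, scan_tab in table.groupby("scan_id"):
            by_roi = {roi: g for roi, g in scan_tab.groupby("roi")}
            for seed_roi in SEED_ROIS:
                for target in TARGET_ROIS:
                    est = bsc(by_roi[seed_roi], by_roi[target], condition)
                    rows.append(
                        {
                            "scan_id": scan_id,
                            "amygdala_roi": seed_roi,
                            "mpfc_roi": target,
                            "gss": gss,
                            "condition": condition,
                            "z": est.estimate,
                        }
                    )
    return pd.DataFrame(rows)


def _slopes_scan_table(lss: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for gss, table in lss.items():
        st = slopes_table(table)
        st["gss"] = gss
        frames.append(st)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------


def run_aim(
    aim: str,
    study: SimulatedStudy,
    grid: dict | None = None,
    seed: int = 0,
    contrast: str = "fear>baseline",
    condition: str = "fear",
    anxiety_table: pd.DataFrame | None = None,
    n_jobs: int = 1,
) -> AimResult:
    """Run one analysis family end to end and summarize its multiverse."""
    if aim not in AIMS:
        raise ValueError(f"unknown aim: {aim!r}")
    if grid is None:
        grid = default_grid("anxiety_reactivity" if aim == "anxiety" else aim)
    specs = enumerate_specs(grid)
    meta = study.scan_table()
    prior_ids = _prior_scan_ids(meta)

    if aim == "reactivity":
        cores = sorted(
            {
                (
                    s.as_dict().get("hrf", "double_gamma"),
                    s.as_dict().get("nuisance", "24"),
                    s.as_dict().get("drift", "highpass_0.01Hz"),
                )
                for s in specs
            }
        )
        scan_tab = _reactivity_scan_table(study, cores)

        def executor(spec: Specification):
            d = spec.as_dict()
            sel = scan_tab[
                (scan_tab["hrf"] == d.get("hrf", "double_gamma"))
                & (scan_tab["nuisance"] == d.get("nuisance", "24"))
                & (scan_tab["drift"] == d.get("drift", "highpass_0.01Hz"))
                & (scan_tab["roi"] == d.get("amygdala_roi", "amyg_bilateral"))
                & (scan_tab["contrast"] == d.get("contrast", contrast))
                & ~scan_tab["excluded"]
            ]
            if d.get("prior_scans", "include") == "exclude":
                sel = sel[~sel["scan_id"].isin(prior_ids)]
            outcome = "beta" if d.get("estimate_type", "beta") == "beta" else "t_stat"
            measures = sel.merge(
                meta.drop(columns=["participant_id", "mean_fd"]), on="scan_id"
            )
            return _fit_group(measures, outcome, d, seed)

    elif aim == "gppi":
        deconv_levels = grid.get("factors", {}).get("deconvolution", ["yes", "no"])
        scan_tab = _gppi_scan_table(study, list(deconv_levels))

        def executor(spec: Specification):
            d = spec.as_dict()
            sel = scan_tab[
                (scan_tab["deconvolution"] == d.get("deconvolution", "no"))
                & (scan_tab["mpfc_roi"] == d.get("mpfc_roi", "mpfc1"))
                & (scan_tab["contrast"] == d.get("contrast", contrast))
            ]
            outcome = "beta" if d.get("estimate_type", "beta") == "beta" else "t"
            measures = sel.merge(meta, on="scan_id")
            return _fit_group(measures, outcome, d, seed)

    elif aim in ("bsc", "trial_dynamics"):
        lss = _lss_tables(study)
        if aim == "bsc":
            scan_tab = _bsc_scan_table(lss, condition)

            def executor(spec: Specification):
                d = spec.as_dict()
                sel = scan_tab[
                    (scan_tab["amygdala_roi"] == d.get("amygdala_roi", "amyg_bilateral"))
                    & (scan_tab["mpfc_roi"] == d.get("mpfc_roi", "mpfc1"))
                    & (scan_tab["gss"] == d.get("gss", "no"))
                ]
                measures = sel.merge(meta, on="scan_id")
                return _fit_group(measures, "z", d, seed)

        else:
            scan_tab = _slopes_scan_table(lss)

            def executor(spec: Specification):
                d = spec.as_dict()
                sel = scan_tab[
                    (scan_tab["roi"] == d.get("amygdala_roi", "amyg_bilateral"))
                    & (scan_tab["condition"] == d.get("condition", condition))
                    & (scan_tab["gss"] == d.get("gss", "no"))
                ]
                measures = sel.merge(meta, on="scan_id")
                return _fit_group(measures, "trial_slope", d, seed)

    else:  # anxiety (reactivity-based brain measures)
        cores = [("double_gamma", "24", "highpass_0.01Hz")]
        scan_tab = _reactivity_scan_table(study, cores)
        if anxiety_table is None:
            anxiety_table = generate_anxiety_scores(
                study.cohort, AnxietyParams(), seed=seed
            )

        def executor(spec: Specification):
            d = spec.as_dict()
            sel = scan_tab[
                (scan_tab["roi"] == d.get("amygdala_roi", "amyg_bilateral"))
                & (scan_tab["contrast"] == d.get("contrast", contrast))
                & ~scan_tab["excluded"]
            ]
            measures = sel.merge(
                meta.drop(columns=["participant_id", "mean_fd"]), on="scan_id"
            ).merge(
                anxiety_table[["participant_id", "wave", d["outcome"]]],
                on=["participant_id", "wave"],
            )
            return fit_brain_anxiety_model(
                measures, "beta", d["outcome"], _group_spec(d), seed=seed
            )

    estimates, failures = run_multiverse(specs, executor, n_jobs=n_jobs)
    curve = build_spec_curve(estimates) if len(estimates) else None
    effects = None
    if len(estimates):
        try:
            effects = decision_effects(estimates)
        except ValueError:
            effects = None
    return AimResult(
        aim=aim, estimates=estimates, failures=failures, curve=curve,
        effects=effects,
    )
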