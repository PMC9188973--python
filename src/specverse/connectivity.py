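"""Task-evoked functional connectivity: gPPI and beta-series correlation.

gPPI regresses a target ROI on psychological (task), physiological (seed
timecourse), and per-condition interaction (PPI) regressors. The
deconvolution fork forms the interaction at the neural scale: the seed
BOLD is deconvolved through a ridge-regularized linear inverse of the HRF
convolution operator, multiplied with the task indicator, and re-convolved.
BSC correlates the per-trial beta series of two ROIs within a condition and
Fisher-z transforms the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .design import CONDITIONS, TaskDesign
from .glm import _estimate_ar1, _wls, censor_weights, detrend_basis
from .hrf import HRFKernel, convolve_series, hrf_at_tr, impulse_train, make_hrf


@dataclass(frozen=True)
class FCEstimate:
    method: str  # "gppi" or "bsc"
    seed: str
    target: str
    contrast: str  # contrast (gppi) or condition (bsc)
    estimate: float  # gppi: beta; bsc: Fisher z
    se: float = np.nan
    fork: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    @property
    def missing(self) -> bool:
        return np.isnan(self.estimate)


@dataclass
class GPPIDesign:
    """Full gPPI design matrix plus censor weights and fork labels."""

    frame: pd.DataFrame
    censor_weights: np.ndarray
    deconvolved: bool
    task_centered: bool
    seed: str = "seed"

    @property
    def ppi_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("ppi_")]


def deconvolve(
    bold_ts: np.ndarray,
    hrf: HRFKernel | str = "double_gamma",
    ridge_lambda: float = 1.0,
    tr: float = 2.0,
) -> np.ndarray:
    """Estimate a neural-scale series n such that conv(H, n) ~ y.

    Solves argmin ||H n - y||^2 + lambda_eff ||n||^2 on the volume grid,
    where H is the causal Toeplitz convolution operator of the TR-sampled
    HRF and lambda_eff scales ``ridge_lambda`` by the mean diagonal of
    H'H so the default is on the signal scale.
    """
    if isinstance(hrf, str):
        hrf = make_hrf(hrf)
    y = np.asarray(bold_ts, dtype=float)
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    n = y.size
    k = hrf_at_tr(hrf, tr)
    H = np.zeros((n, n))
    for i in range(min(k.size, n)):
        H += np.diag(np.full(n - i, k[i]), -i)
    A = H.T @ H
    lam = ridge_lambda * np.trace(A) / n
    return np.linalg.solve(A + lam * np.eye(n), H.T @ y)


def _task_indicator_at_tr(
    design: TaskDesign, condition: str, dt: float = 0.1
) -> np.ndarray:
    """Condition event indicator averaged within each TR (350 ms impulses
    sampled on a fine grid, then block-averaged to the volume grid)."""
    mask = design.trial_conditions == condition
    fine = impulse_train(
        design.trial_onsets[mask],
        design.trial_durations[mask],
        np.ones(mask.sum()),
        design.run_length,
        dt,
    )
    per_tr = int(round(design.tr / dt))
    return fine[: design.n_volumes * per_tr].reshape(design.n_volumes, per_tr).mean(
        axis=1
    )


def build_gppi_design(
    seed_ts: np.ndarray | pd.Series,
    design: TaskDesign,
    hrf: HRFKernel | str = "double_gamma",
    deconvolve_seed: bool = False,
    center_task: bool = False,
    nuisance: pd.DataFrame | None = None,
    fd_series: np.ndarray | None = None,
    drift: str = "highpass_0.01Hz",
    ridge_lambda: float = 1.0,
) -> GPPIDesign:
    """Assemble psych, physio, and per-condition PPI regressors.

    Without deconvolution the PPI term is the (mean-removed) seed times the
    convolved task regressor; with deconvolution it is the re-convolved
    product of the deconvolved seed and the task indicator. ``center_task``
    mean-centers the task term entering the product only — the psych
    columns themselves are unchanged.
    """
    if isinstance(hrf, str):
        hrf = make_hrf(hrf)
    seed_name = getattr(seed_ts, "name", None) or "seed"
    y = np.asarray(seed_ts, dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("seed timeseries is constant: degenerate physio term")
    physio = y - y.mean()
    cols: dict[str, np.ndarray] = {}
    from .hrf import convolve_events

    for cond in CONDITIONS:
        mask = design.trial_conditions == cond
        cols[f"psych_{cond}"] = convolve_events(
            design.trial_onsets[mask],
            design.trial_durations[mask],
            np.ones(mask.sum()),
            hrf,
            design.tr,
            design.n_volumes,
        )
    if deconvolve_seed:
        neural = deconvolve(physio, hrf, ridge_lambda, tr=design.tr)
        k = hrf_at_tr(hrf, design.tr)
        for cond in CONDITIONS:
            task = _task_indicator_at_tr(design, cond)
            if center_task:
                task = task - task.mean()
            cols[f"ppi_{cond}"] = convolve_series(neural * task, k)
    else:
        for cond in CONDITIONS:
            task = cols[f"psych_{cond}"]
            if center_task:
                task = task - task.mean()
            cols[f"ppi_{cond}"] = physio * task
    cols["physio"] = physio
    frame = pd.DataFrame(cols)
    frame["intercept"] = 1.0
    frame = pd.concat(
        [frame, detrend_basis(drift, design.n_volumes, design.tr)], axis=1
    )
    if nuisance is not None:
        frame = pd.concat([frame, nuisance.reset_index(drop=True)], axis=1)
    if fd_series is not None:
        weights, _ = censor_weights(fd_series)
    else:
        weights = np.ones(design.n_volumes)
    return GPPIDesign(
        frame=frame,
        censor_weights=weights,
        deconvolved=deconvolve_seed,
        task_centered=center_task,
        seed=str(seed_name),
    )


_PPI_COLLINEARITY_R = 0.95


def fit_gppi(
    target_ts: np.ndarray | pd.Series,
    gppi_design: GPPIDesign,
    prewhiten: str = "ar1",
) -> list[FCEstimate]:
    """GLM of the target on the gPPI design; returns contrasts on the PPI
    betas plus the physio (task-independent FC) beta."""
    y = np.asarray(target_ts, dtype=float)
    target_name = getattr(target_ts, "name", None) or "target"
    names = list(gppi_design.frame.columns)
    X = gppi_design.frame.to_numpy(dtype=float)
    w = gppi_design.censor_weights.astype(float)
    flags: list[str] = []
    for cond in CONDITIONS:
        ppi = gppi_design.frame[f"ppi_{cond}"]
        psych = gppi_design.frame[f"psych_{cond}"]
        if ppi.std() > 0 and psych.std() > 0:
            r = float(np.corrcoef(ppi, psych)[0, 1])
            if abs(r) > _PPI_COLLINEARITY_R:
                flags.append(f"ppi_psych_collinear_{cond}")
    beta, cov_u, sigma2, dof = _wls(y, X, w)
    if prewhiten == "ar1":
        resid = y - X @ beta
        rho = _estimate_ar1(resid, w)
        if abs(rho) > 1e-8:
            beta, cov_u, sigma2, dof = _wls(
                y[1:] - rho * y[:-1],
                X[1:] - rho * X[:-1],
                np.minimum(w[1:], w[:-1]),
            )
    fork = {
        "deconvolution": gppi_design.deconvolved,
        "task_centered": gppi_design.task_centered,
    }
    idx = {name: i for i, name in enumerate(names)}
    out = []

    def _contrast(c: np.ndarray, label: str) -> FCEstimate:
        est = float(c @ beta)
        se = (
            float(np.sqrt(sigma2 * c @ cov_u @ c))
            if np.isfinite(sigma2) and sigma2 > 0
            else np.nan
        )
        return FCEstimate(
            method="gppi",
            seed=gppi_design.seed,
            target=str(target_name),
            contrast=label,
            estimate=est,
            se=se,
            fork=fork,
            flags=tuple(flags),
        )

    for cond in CONDITIONS:
        c = np.zeros(len(names))
        c[idx[f"ppi_{cond}"]] = 1.0
        out.append(_contrast(c, f"{cond}>baseline"))
    c = np.zeros(len(names))
    c[idx["ppi_fear"]], c[idx["ppi_neutral"]] = 1.0, -1.0
    out.append(_contrast(c, "fear>neutral"))
    c = np.zeros(len(names))
    c[idx["physio"]] = 1.0
    out.append(_contrast(c, "physio"))
    return out


_CLAMP_R = 1.0 - 1e-6


def bsc(
    seed_series: pd.DataFrame,
    target_series: pd.DataFrame,
    condition: str,
) -> FCEstimate:
    """Fisher-z beta-series correlation between two ROIs for one condition.

    Expects per-ROI beta tables (columns condition, trial_index, beta);
    pairs trials on trial index, requires >= 4 non-missing pairs. |r| = 1
    is flagged and clamped at 1 - 1e-6 before the transform; zero-variance
    series yield a missing estimate with a degeneracy flag.
    """
    seed_roi = seed_series["roi"].iloc[0] if "roi" in seed_series else "seed"
    target_roi = target_series["roi"].iloc[0] if "roi" in target_series else "target"
    fork = {
        "gss": bool(seed_series.get("gss_applied", pd.Series([False])).iloc[0]),
    }
    a = seed_series[seed_series["condition"] == condition][["trial_index", "beta"]]
    b = target_series[target_series["condition"] == condition][
        ["trial_index", "beta"]
    ]
    merged = a.merge(b, on="trial_index", suffixes=("_seed", "_target")).dropna()
    if len(merged) < 4:
        return FCEstimate(
            "bsc", seed_roi, target_roi, condition, np.nan, fork=fork,
            flags=("too_few_trials",),
        )
    x = merged["beta_seed"].to_numpy()
    y = merged["beta_target"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return FCEstimate(
            "bsc", seed_roi, target_roi, condition, np.nan, fork=fork,
            flags=("zero_variance",),
        )
    r = float(np.corrcoef(x, y)[0, 1])
    flags: tuple[str, ...] = ()
    if abs(r) >= _CLAMP_R:
        flags = ("perfect_correlation_clamped",)
        r = np.sign(r) * _CLAMP_R
    return FCEstimate(
        "bsc", seed_roi, target_roi, condition, float(np.arctanh(r)),
        fork=fork, flags=flags,
    )


def fc_method_concordance(fc_table: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix of scan-level FC estimates across
    method/fork columns.

    ``fc_table``: one row per (scan_id, column) in long form with columns
    scan_id, label, estimate — or a wide table indexed by scan_id.
    """
    if {"scan_id", "label", "estimate"}.issubset(fc_table.columns):
        wide = fc_table.pivot(index="scan_id", columns="label", values="estimate")
    else:
        wide = fc_table
    labels = list(wide.columns)
    if len(wide) < 3:
        raise ValueError("need at least 3 scans for concordance")
    mat = np.eye(len(labels))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = wide[[labels[i], labels[j]]].dropna()
            rho = spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=labels, columns=labels)
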