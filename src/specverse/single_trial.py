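"""Least-squares-separate (LSS) single-trial betas and within-scan dynamics.

Each of the 48 trials gets its own GLM in which the target trial has a
dedicated regressor and the remaining 47 trials share one regressor, plus
the same nuisance/drift/censoring structure as the condition-level GLM.
Within-scan change is summarized per condition as the rank-order (Spearman)
correlation of beta with trial number and as first-half / second-half mean
betas. A global-signal correction (post hoc distribution centering) removes
the across-ROI mean beta from each trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .glm import censor_weights, detrend_basis, expand_motion_regressors
from .hrf import HRFKernel, convolve_events, make_hrf
from .simulate import ROI_PANEL, ScanRecord

BETA_COLUMNS = ["scan_id", "roi", "condition", "trial_index", "beta", "gss_applied"]


def _wls_beta(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)[:, None]
    return np.linalg.lstsq(X * sw, y * sw[:, 0, None], rcond=None)[0]


def fit_lss(
    scan: ScanRecord,
    rois: tuple[str, ...] = ROI_PANEL,
    hrf: HRFKernel | str = "double_gamma",
    nuisance_set: str = "24",
    drift: str = "highpass_0.01Hz",
    include_intercept: bool = True,
) -> pd.DataFrame:
    """Per-trial betas for every requested ROI (tidy long table).

    A trial whose regressor support is entirely censored yields a missing
    (NaN) beta rather than a spurious estimate. ``nuisance_set`` and
    ``drift`` accept ``"none"`` for stripped-down designs (exact-oracle
    comparisons); the default matches the condition-level GLM.
    """
    if isinstance(hrf, str):
        hrf = make_hrf(hrf)
    design = scan.design
    n = design.n_trials
    tissue = (
        scan.roi_timeseries[["wm", "csf"]] if nuisance_set == "18+WM+CSF" else None
    )
    n_vol = design.n_volumes
    drift_cols = (
        np.empty((n_vol, 0))
        if drift == "none"
        else detrend_basis(drift, n_vol, design.tr).to_numpy()
    )
    nuis = (
        np.empty((n_vol, 0))
        if nuisance_set == "none"
        else expand_motion_regressors(
            scan.realignment_params, nuisance_set, tissue
        ).to_numpy()
    )
    weights, _ = censor_weights(scan.fd_series)
    Y = scan.roi_timeseries[list(rois)].to_numpy(dtype=float)
    intercept = np.ones((n_vol, 1)) if include_intercept else np.empty((n_vol, 0))
    # unit-amplitude single-event regressors, reused across the 48 models
    single = np.column_stack(
        [
            convolve_events(
                design.trial_onsets[[k]],
                design.trial_durations[[k]],
                np.ones(1),
                hrf,
                design.tr,
                design.n_volumes,
            )
            for k in range(n)
        ]
    )
    all_trials = single.sum(axis=1)
    rows = []
    for k in range(n):
        target = single[:, k]
        support = np.abs(target) > 0.05 * np.abs(target).max()
        fully_censored = not np.any(weights[support] > 0)
        others = all_trials - target
        X = np.column_stack([target, others, intercept, drift_cols, nuis])
        if fully_censored:
            betas = np.full(len(rois), np.nan)
        else:
            betas = _wls_beta(Y, X, weights)[0]
        for roi, b in zip(rois, betas):
            rows.append(
                {
                    "scan_id": scan.scan_id,
                    "roi": roi,
                    "condition": design.trial_conditions[k],
                    "trial_index": int(design.trial_index[k]),
                    "beta": float(b),
                    "gss_applied": False,
                }
            )
    return pd.DataFrame(rows, columns=BETA_COLUMNS)


def apply_global_signal_centering(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Post hoc distribution centering: subtract, for every trial, the mean
    beta across the ROI panel from each ROI's beta.

    Invariant to adding a common per-trial offset to all ROIs; pairwise
    between-ROI differences are preserved exactly.
    """
    if beta_table["roi"].nunique() < 2:
        raise ValueError("global-signal centering needs at least two ROIs")
    out = beta_table.copy()
    keys = ["scan_id", "condition", "trial_index"]
    means = out.groupby(keys)["beta"].transform("mean")
    out["beta"] = out["beta"] - means
    out["gss_applied"] = True
    return out


@dataclass(frozen=True)
class SlopeResult:
    """Rank-order correlation of beta with trial number for one condition."""

    value: float
    n: int
    degenerate: bool = False
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return np.isnan(self.value)


def trial_slope(series: pd.DataFrame, condition: str) -> SlopeResult:
    """Spearman correlation of beta vs trial index (ties mid-ranked).

    A constant beta series returns 0 with the degeneracy flag; fewer than
    3 usable trials returns missing with a reason.
    """
    sub = series[(series["condition"] == condition) & series["beta"].notna()]
    if len(sub) < 3:
        return SlopeResult(np.nan, len(sub), reason="fewer than 3 usable trials")
    betas = sub["beta"].to_numpy()
    if np.allclose(betas, betas[0]):
        return SlopeResult(0.0, len(sub), degenerate=True, reason="constant betas")
    rho = spearmanr(sub["trial_index"].to_numpy(), betas).statistic
    return SlopeResult(float(rho), len(sub))


def half_means(
    series: pd.DataFrame, condition: str, n_trials_per_condition: int = 24
) -> tuple[float, float, int, int]:
    """Mean beta over trials 1-12 and 13-24 (missing betas ignored).

    Returns (first_mean, second_mean, n_first, n_second); an empty half
    yields NaN for that half.
    """
    half = n_trials_per_condition // 2
    sub = series[(series["condition"] == condition) & series["beta"].notna()]
    first = sub[sub["trial_index"] <= half]["beta"]
    second = sub[sub["trial_index"] > half]["beta"]
    m1 = float(first.mean()) if len(first) else np.nan
    m2 = float(second.mean()) if len(second) else np.nan
    return m1, m2, len(first), len(second)


def slopes_table(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Per (scan, roi, condition) Spearman slope summary of a beta table."""
    rows = []
    for (scan_id, roi, cond), grp in beta_table.groupby(
        ["scan_id", "roi", "condition"]
    ):
        res = trial_slope(grp, cond)
        rows.append(
            {
                "scan_id": scan_id,
                "roi": roi,
                "condition": cond,
                "trial_slope": res.value,
                "n_trials": res.n,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def halves_table(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Per (scan, roi, condition, half) mean-beta table (long format)."""
    rows = []
    for (scan_id, roi, cond), grp in beta_table.groupby(
        ["scan_id", "roi", "condition"]
    ):
        m1, m2, n1, n2 = half_means(grp, cond)
        for half, m, cnt in (("first", m1, n1), ("second", m2, n2)):
            rows.append(
                {
                    "scan_id": scan_id,
                    "roi": roi,
                    "condition": cond,
                    "half": half,
                    "mean_beta": m,
                    "n_trials": cnt,
                }
            )
    return pd.DataFrame(rows)
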