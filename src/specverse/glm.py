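"""Scan-level GLM estimation of condition contrasts from ROI timeseries.

Implements the participant-level forks of the multiverse: HRF shape
(double vs single gamma), nuisance-regressor sets (6 / 24 motion
regressors, or 18 + WM + CSF tissue signals), low-frequency drift removal
(0.01 Hz discrete-cosine high-pass basis or polynomial drift regressors),
motion censoring (FD > 0.9 mm volumes downweighted to 0, scans with more
than 40 such volumes excluded), optional AR(1) prewhitening, and beta vs
t-statistic contrast outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITIONS, TaskDesign
from .hrf import HRFKernel, convolve_events, make_hrf

FD_THRESHOLD_MM = 0.9
MAX_CENSORED_VOLUMES = 40
CONTRASTS = ("fear>baseline", "neutral>baseline", "fear>neutral")
NUISANCE_SETS = ("6", "24", "18+WM+CSF")


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; message names suspect columns."""


@dataclass(frozen=True)
class ContrastEstimate:
    contrast: str
    roi: str
    beta: float
    se: float
    t_stat: float
    dof: float
    degenerate: bool = False  # zero-residual fit: t undefined

    def __post_init__(self) -> None:
        if self.se > 0 and not np.isnan(self.t_stat):
            assert np.sign(self.t_stat) == np.sign(self.beta) or self.beta == 0


@dataclass
class DesignMatrix:
    """Named design columns plus per-volume 0/1 censor weights."""

    frame: pd.DataFrame
    censor_weights: np.ndarray
    scan_excluded: bool = False
    task_columns: tuple[str, ...] = ("fear", "neutral")

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("design column names must be unique")
        for c in self.task_columns:
            if np.allclose(self.frame[c].to_numpy(), 0.0):
                raise ValueError(f"task column {c!r} is all zero")
        if len(self.censor_weights) != len(self.frame):
            raise ValueError("censor weights length must equal n_volumes")


def expand_motion_regressors(
    realignment_params: pd.DataFrame | np.ndarray,
    nuisance_set: str = "24",
    tissue: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand 6 realignment parameters into the requested nuisance set.

    ``"6"``: the raw parameters. ``"24"``: parameters, their backward-
    difference temporal derivatives, and the squares of those 12.
    ``"18+WM+CSF"``: parameters, derivatives, squares of the parameters,
    plus white-matter and CSF tissue-signal columns.
    """
    rp = pd.DataFrame(realignment_params).copy()
    if rp.shape[1] != 6:
        raise ValueError("expected exactly 6 realignment parameter columns")
    rp.columns = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    if nuisance_set == "6":
        return rp.reset_index(drop=True)
    deriv = rp.diff().fillna(0.0)
    deriv.columns = [f"{c}_deriv" for c in rp.columns]
    if nuisance_set == "24":
        twelve = pd.concat(
            [rp.reset_index(drop=True), deriv.reset_index(drop=True)], axis=1
        )
        squares = twelve**2
        squares.columns = [f"{c}_sq" for c in twelve.columns]
        return pd.concat([twelve, squares], axis=1)
    if nuisance_set == "18+WM+CSF":
        squares = rp.reset_index(drop=True) ** 2
        squares.columns = [f"{c}_sq" for c in rp.columns]
        out = pd.concat(
            [rp.reset_index(drop=True), deriv.reset_index(drop=True), squares],
            axis=1,
        )
        if tissue is None:
            raise ValueError("tissue signals required for the 18+WM+CSF set")
        out["wm"] = np.asarray(tissue["wm"], dtype=float)
        out["csf"] = np.asarray(tissue["csf"], dtype=float)
        return out
    raise ValueError(f"unknown nuisance set: {nuisance_set!r}")


def censor_weights(
    fd_series: np.ndarray, threshold_mm: float = FD_THRESHOLD_MM
) -> tuple[np.ndarray, bool]:
    """Per-volume 0/1 weights and the scan-exclusion flag.

    Volumes with FD strictly greater than the threshold get weight 0; the
    scan is flagged excluded when more than 40 volumes exceed it.
    """
    fd = np.asarray(fd_series, dtype=float)
    if np.any(fd < 0):
        raise ValueError("fd_series must be non-negative")
    over = fd > threshold_mm
    weights = np.where(over, 0.0, 1.0)
    return weights, bool(over.sum() > MAX_CENSORED_VOLUMES)


def detrend_basis(kind: str, n_volumes: int, tr: float) -> pd.DataFrame:
    """Low-frequency drift columns (intercept excluded, added by the GLM).

    ``highpass_0.01Hz``: discrete-cosine basis with floor(2 T f) columns,
    a deterministic regressor substitute for a running-line filter.
    ``quadratic``: orthogonalized linear and quadratic time trends.
    """
    if n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    t = np.arange(n_volumes)
    if kind == "highpass_0.01Hz":
        total = n_volumes * tr
        k_max = int(np.floor(2 * total * 0.01))
        cols = {
            f"dct{k}": np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
            for k in range(1, k_max + 1)
        }
        return pd.DataFrame(cols)
    if kind == "quadratic":
        lin = t - t.mean()
        quad = lin**2
        quad = quad - quad.mean()
        quad = quad - (quad @ lin) / (lin @ lin) * lin
        return pd.DataFrame({"drift_lin": lin, "drift_quad": quad})
    raise ValueError(f"unknown detrend kind: {kind!r}")


def build_design_matrix(
    design: TaskDesign,
    realignment_params: pd.DataFrame,
    fd_series: np.ndarray,
    hrf: HRFKernel | str = "double_gamma",
    nuisance_set: str = "24",
    drift: str = "highpass_0.01Hz",
    tissue: pd.DataFrame | None = None,
    include_derivatives: bool = True,
) -> DesignMatrix:
    """Assemble the full scan-level design: task regressors (one per
    condition, convolved with the HRF), their temporal derivatives
    (backward differences of the convolved regressors), an intercept,
    drift columns, and the nuisance set."""
    if isinstance(hrf, str):
        hrf = make_hrf(hrf)
    cols: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        mask = design.trial_conditions == cond
        reg = convolve_events(
            design.trial_onsets[mask],
            design.trial_durations[mask],
            np.ones(mask.sum()),
            hrf,
            design.tr,
            design.n_volumes,
        )
        cols[cond] = reg
    if include_derivatives:
        for cond in CONDITIONS:
            d = np.diff(cols[cond], prepend=cols[cond][0])
            cols[f"{cond}_deriv"] = d
    frame = pd.DataFrame(cols)
    frame["intercept"] = 1.0
    frame = pd.concat(
        [
            frame,
            detrend_basis(drift, design.n_volumes, design.tr),
            expand_motion_regressors(realignment_params, nuisance_set, tissue),
        ],
        axis=1,
    )
    weights, excluded = censor_weights(fd_series)
    return DesignMatrix(frame=frame, censor_weights=weights, scan_excluded=excluded)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns pivoted last with tiny diagonal are the culprits
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(names)) if diag[i] < tol]
        raise SingularDesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect columns: {bad}"
        )


def _wls(
    y: np.ndarray, X: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Weighted least squares; returns (beta, cov_unscaled, sigma2, dof)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    XtX = Xw.T @ Xw
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    dof = float((w > 0).sum() - X.shape[1])
    sigma2 = float(resid @ resid / dof) if dof > 0 else np.nan
    return beta, XtX_inv, sigma2, dof


def _estimate_ar1(resid: np.ndarray, w: np.ndarray) -> float:
    keep = w > 0
    r = resid[keep]
    if r.size < 3 or np.allclose(r, 0):
        return 0.0
    num = float(r[1:] @ r[:-1])
    den = float(r @ r)
    return float(np.clip(num / den, -0.95, 0.95))


def fit_glm(
    roi_ts: np.ndarray | pd.Series | pd.DataFrame,
    design: DesignMatrix,
    prewhiten: str = "ar1",
) -> dict[str, ContrastEstimate] | dict[str, dict[str, ContrastEstimate]]:
    """Fit the scan GLM and return the three condition contrasts.

    Weighted least squares with the design's censor weights; ``ar1``
    prewhitening is a single-lag Cochrane-Orcutt pass (estimate the lag-1
    residual autocorrelation, quasi-difference y and X, refit). A 2-D input
    (volumes x ROIs) returns a mapping ROI -> contrast estimates.
    """
    if isinstance(roi_ts, pd.DataFrame):
        return {
            roi: fit_glm(roi_ts[roi], design, prewhiten)
            for roi in roi_ts.columns
        }
    y = np.asarray(roi_ts, dtype=float)
    names = list(design.frame.columns)
    X = design.frame.to_numpy(dtype=float)
    w = design.censor_weights.astype(float)
    if (w > 0).sum() < X.shape[1] + 2:
        raise ValueError("too few uncensored volumes to fit the design")
    _check_rank(X[w > 0], names)
    roi_name = getattr(roi_ts, "name", "roi") or "roi"
    beta, cov_u, sigma2, dof = _wls(y, X, w)
    if prewhiten == "ar1":
        resid = y - X @ beta
        rho = _estimate_ar1(resid, w)
        if abs(rho) > 1e-8:
            y2 = y[1:] - rho * y[:-1]
            X2 = X[1:] - rho * X[:-1]
            w2 = np.minimum(w[1:], w[:-1])
            beta, cov_u, sigma2, dof = _wls(y2, X2, w2)
    elif prewhiten != "none":
        raise ValueError(f"unknown prewhiten option: {prewhiten!r}")
    i_f, i_n = names.index("fear"), names.index("neutral")
    y_scale = float(np.var(y[design.censor_weights > 0]))
    degenerate = not np.isfinite(sigma2) or sigma2 < 1e-16 * max(y_scale, 1e-300)
    out = {}
    for contrast in CONTRASTS:
        c = np.zeros(len(names))
        if contrast == "fear>baseline":
            c[i_f] = 1.0
        elif contrast == "neutral>baseline":
            c[i_n] = 1.0
        else:
            c[i_f], c[i_n] = 1.0, -1.0
        est = float(c @ beta)
        if degenerate:
            se, t = 0.0, np.nan
        else:
            se = float(np.sqrt(sigma2 * c @ cov_u @ c))
            t = est / se if se > 0 else np.nan
        out[contrast] = ContrastEstimate(
            contrast=contrast,
            roi=str(roi_name),
            beta=est,
            se=se,
            t_stat=t,
            dof=dof,
            degenerate=degenerate,
        )
    return out


def fit_scan_contrasts(
    scan,
    rois: tuple[str, ...] = ("amyg_bilateral", "amyg_left", "amyg_right"),
    hrf_kind: str = "double_gamma",
    nuisance_set: str = "24",
    drift: str = "highpass_0.01Hz",
    prewhiten: str = "ar1",
) -> pd.DataFrame:
    """Tidy contrast table for one scan under one participant-level fork."""
    tissue = scan.roi_timeseries[["wm", "csf"]] if nuisance_set == "18+WM+CSF" else None
    dm = build_design_matrix(
        scan.design,
        scan.realignment_params,
        scan.fd_series,
        hrf=hrf_kind,
        nuisance_set=nuisance_set,
        drift=drift,
        tissue=tissue,
    )
    rows = []
    for roi in rois:
        fits = fit_glm(scan.roi_timeseries[roi], design=dm, prewhiten=prewhiten)
        for contrast, est in fits.items():
            rows.append(
                {
                    "scan_id": scan.scan_id,
                    "participant_id": scan.participant_id,
                    "roi": roi,
                    "contrast": contrast,
                    "beta": est.beta,
                    "se": est.se,
                    "t_stat": est.t_stat,
                    "dof": est.dof,
                    "mean_fd": scan.mean_fd,
                    "excluded": dm.scan_excluded,
                }
            )
    return pd.DataFrame(rows)
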