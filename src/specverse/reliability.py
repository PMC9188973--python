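"""Longitudinal test-retest reliability via variance-decomposition ICC.

The ICC of a scan-level measure is the fraction of its variance explained
by stable between-participant differences, estimated from the same
multilevel model used for the measure's group-level analysis (mean-FD
covariate included by default, removable). Two methods: a fast
variance-components path (sigma2_between / total from a random-intercept
REML fit, participant-bootstrap interval) and a posterior-predictive path
(1 - var(PPD | random effects) / var(PPD marginal) averaged over posterior
draws, which tolerates missing visits and can be negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bayes import PriorSpec, fit_lmm_bayes
from .group_models import _mixedlm_reml

BAND_THRESHOLDS = ((0.4, "poor"), (0.6, "fair"), (0.75, "good"))


def band(icc_value: float) -> str:
    """Reliability band: poor < .4, fair [.4, .6), good [.6, .75),
    excellent >= .75. Negative values are poor."""
    if not np.isfinite(icc_value):
        raise ValueError("ICC value must be finite")
    for upper, label in BAND_THRESHOLDS:
        if icc_value < upper:
            return label
    return "excellent"


@dataclass(frozen=True)
class ICCEstimate:
    measure: str
    icc: float
    lower: float
    upper: float
    method: str
    n_participants: int
    n_scans: int
    missing: bool = False
    reason: str | None = None

    @property
    def reliability_band(self) -> str:
        return band(self.icc)


def _design(df: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for cov in covariates:
        X[cov] = df[cov].astype(float)
    return X


def _vc_point(df: pd.DataFrame, measure: str, covariates: tuple[str, ...]) -> float:
    X = _design(df, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            df[measure].to_numpy(dtype=float), X, groups=df["participant_id"].to_numpy()
        )
        res = _mixedlm_reml(model)
    var_b = float(res.cov_re.iloc[0, 0])
    var_w = float(res.scale)
    return var_b / (var_b + var_w)


def icc_variance_components(
    scan_table: pd.DataFrame,
    measure: str,
    covariates: tuple[str, ...] = ("mean_fd",),
    method: str = "variance_components",
    seed: int = 0,
    n_boot: int = 500,
    bayes_kwargs: dict | None = None,
) -> ICCEstimate:
    """ICC of a scan-level measure with 95% interval.

    All participants are retained, including single-visit ones (they still
    inform the residual variance). The posterior-predictive method computes,
    per posterior draw, 1 - var(simulated data conditional on random
    effects) / var(simulated data marginally); sampling noise in the finite
    simulated vectors makes negative draws (and estimates) possible.
    """
    df = scan_table.dropna(subset=[measure]).copy()
    n_parts = df["participant_id"].nunique()
    n_scans = len(df)
    multi = (df.groupby("participant_id")[measure].count() >= 2).sum()
    if multi < 2:
        raise ValueError("need at least 2 participants with 2+ scans")
    if df[measure].std() == 0:
        return ICCEstimate(
            measure, np.nan, np.nan, np.nan, method, n_parts, n_scans,
            missing=True, reason="zero total variance",
        )
    if method == "variance_components":
        point = _vc_point(df, measure, covariates)
        rng = np.random.default_rng(seed)
        participants = df["participant_id"].unique()
        boots = []
        grouped = {p: g for p, g in df.groupby("participant_id")}
        for _ in range(n_boot):
            chosen = rng.choice(participants, size=len(participants), replace=True)
            parts = []
            for i, p in enumerate(chosen):
                g = grouped[p].copy()
                g["participant_id"] = f"boot{i}"
                parts.append(g)
            bdf = pd.concat(parts, ignore_index=True)
            if (bdf.groupby("participant_id")[measure].count() >= 2).sum() < 2:
                continue
            try:
                boots.append(_vc_point(bdf, measure, covariates))
            except (np.linalg.LinAlgError, ValueError):
                continue
        if boots:
            lo, hi = np.quantile(boots, [0.025, 0.975])
        else:
            lo = hi = np.nan
        return ICCEstimate(
            measure, float(point), float(lo), float(hi), method, n_parts, n_scans
        )
    if method != "posterior_predictive":
        raise ValueError(f"unknown ICC method: {method!r}")
    X = _design(df, covariates)
    bres = fit_lmm_bayes(
        df[measure].to_numpy(dtype=float),
        X,
        df["participant_id"].to_numpy(),
        prior=PriorSpec(),
        seed=seed,
        **(bayes_kwargs or {}),
    )
    rng = np.random.default_rng(seed + 1)
    draws = bres.draws
    n_draws = min(400, len(draws))
    idx = rng.choice(len(draws), size=n_draws, replace=False)
    Xv = X.to_numpy(dtype=float)
    part_codes = pd.factorize(df["participant_id"])[0]
    iccs = np.empty(n_draws)
    for i, d in enumerate(idx):
        beta = draws.iloc[d][list(X.columns)].to_numpy(dtype=float)
        sigma = float(draws.iloc[d]["sigma"])
        tau = float(draws.iloc[d]["tau_participant"])
        mu = Xv @ beta
        b = rng.normal(0.0, tau, part_codes.max() + 1)[part_codes]
        y_marg = mu + b + rng.normal(0.0, sigma, len(mu))
        y_cond = mu + rng.normal(0.0, sigma, len(mu))
        iccs[i] = 1.0 - np.var(y_cond) / np.var(y_marg)
    lo, hi = np.quantile(iccs, [0.025, 0.975])
    return ICCEstimate(
        measure, float(np.mean(iccs)), float(lo), float(hi),
        "posterior_predictive", n_parts, n_scans,
    )
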