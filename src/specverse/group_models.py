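"""Multilevel longitudinal models for scan-level brain measures.

Age-related change in any scan-level measure is modeled with participant
random intercepts (optionally random age slopes), a mean-FD head-motion
covariate in every model, and optional block-order and scanner covariates.
Age enters linearly, quadratically, or as 1/age, centered at 12 years;
a within/between parametrization splits age into each participant's mean
age and the deviation from it. Estimation is either a fast frequentist
path (REML via statsmodels MixedLM, or marginal ML with a student-t
observation model for robust fits) or ensemble-MCMC Bayesian with weakly
informative student-t priors. The outlier forks drop observations more
than 3 SD from the mean of the measure before modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize

from .bayes import PriorSpec, _MarginalLMM, fit_lmm_bayes
from .cohort import AGE_CENTER

AGE_FORMS = ("linear", "quadratic", "inverse")
OUTLIER_RULES = ("none", "exclude_3sd", "exclude_3sd_plus_robust")
COVARIATE_SETS = {
    "mean_fd": (),
    "mean_fd+block": ("block",),
    "mean_fd+scanner": ("scanner",),
    "mean_fd+block+scanner": ("block", "scanner"),
}


@dataclass(frozen=True)
class AgeModelSpec:
    """One group-level model specification (a single multiverse fork)."""

    age_form: str = "linear"
    covariates: str = "mean_fd"  # key into COVARIATE_SETS; mean FD always in
    random_slopes: bool = False
    robust: bool = False
    outlier_rule: str = "exclude_3sd"
    parametrization: str = "pooled_age"  # or "within_between"
    estimation: str = "fast_freq"  # or "bayes_mcmc"

    def __post_init__(self) -> None:
        if self.age_form not in AGE_FORMS:
            raise ValueError(f"unknown age form: {self.age_form!r}")
        if self.covariates not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate set: {self.covariates!r}")
        if self.outlier_rule not in OUTLIER_RULES:
            raise ValueError(f"unknown outlier rule: {self.outlier_rule!r}")


@dataclass(frozen=True)
class GroupEstimate:
    """A fitted term with its 95% uncertainty interval."""

    term: str
    estimate: float
    lower: float
    upper: float
    n_scans: int
    n_participants: int
    method: str = "fast_freq"
    fork_id: str = ""
    converged: bool = True
    inestimable: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.estimate) and np.isfinite(self.lower):
            assert self.lower <= self.estimate <= self.upper

    @property
    def excludes_zero(self) -> bool:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            return False
        return not (self.lower <= 0.0 <= self.upper)

    @property
    def sign(self) -> int:
        return int(np.sign(self.estimate))


def exclude_outliers(
    values: pd.Series, rule: str = "exclude_3sd"
) -> tuple[pd.Series, list]:
    """Drop observations more than 3 SD from the mean of the measure.

    SD is computed over all supplied scan-level estimates; a zero-SD
    (constant) input excludes nothing. Returns the filtered series and the
    index labels of excluded observations.
    """
    if rule == "none":
        return values, []
    if rule not in OUTLIER_RULES:
        raise ValueError(f"unknown outlier rule: {rule!r}")
    v = values.dropna()
    if len(v) < 3:
        return values, []
    mu, sd = v.mean(), v.std(ddof=0)
    if sd == 0:
        return values, []
    keep = (values - mu).abs() <= 3 * sd
    keep |= values.isna()
    excluded = list(values.index[~keep])
    return values[keep], excluded


# ---------------------------------------------------------------------------
# design construction


def _age_columns(df: pd.DataFrame, spec: AgeModelSpec) -> tuple[pd.DataFrame, list[str]]:
    out = pd.DataFrame(index=df.index)
    age = df["age_at_scan"].astype(float)
    if spec.parametrization == "within_between":
        pm = age.groupby(df["participant_id"]).transform("mean")
        out["age_between"] = pm - AGE_CENTER
        out["age_within"] = age - pm
        terms = ["age_between", "age_within"]
    elif spec.age_form == "linear":
        out["age"] = age - AGE_CENTER
        terms = ["age"]
    elif spec.age_form == "quadratic":
        out["age"] = age - AGE_CENTER
        out["age2"] = (age - AGE_CENTER) ** 2
        terms = ["age", "age2"]
    else:  # inverse
        out["inv_age"] = 1.0 / age
        terms = ["inv_age"]
    return out, terms


def _covariate_columns(df: pd.DataFrame, spec: AgeModelSpec) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["mean_fd"] = df["mean_fd"].astype(float)
    for cov in COVARIATE_SETS[spec.covariates]:
        col = "block_order" if cov == "block" else "scanner"
        dummies = pd.get_dummies(df[col], prefix=cov, drop_first=True, dtype=float)
        out = pd.concat([out, dummies], axis=1)
    return out


def _design(
    df: pd.DataFrame, spec: AgeModelSpec
) -> tuple[pd.DataFrame, list[str]]:
    age_cols, terms = _age_columns(df, spec)
    X = pd.concat(
        [pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index), age_cols,
         _covariate_columns(df, spec)],
        axis=1,
    )
    return X, terms


# ---------------------------------------------------------------------------
# estimation paths


def _mixedlm_reml(model: sm.MixedLM):
    """REML fit with an optimizer fallback chain (lbfgs can hit singular
    working matrices on boundary fits)."""
    last_exc = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            return model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise last_exc


def _fit_freq_mixedlm(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    slope_col: str | None,
) -> tuple[dict[str, tuple[float, float]], bool]:
    """REML mixed model; returns {term: (estimate, se)} and convergence."""
    if slope_col is not None:
        exog_re = X[["intercept", slope_col]]
    else:
        exog_re = X[["intercept"]]
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        res = _mixedlm_reml(model)
    converged = bool(getattr(res, "converged", True)) and not any(
        "did not converge" in str(w.message).lower() for w in wlist
    )
    out = {}
    for term in X.columns:
        se = float(res.bse_fe[term]) if np.isfinite(res.bse_fe[term]) else np.nan
        out[term] = (float(res.fe_params[term]), se)
    if not all(np.isfinite(se) for _, se in out.values()):
        converged = False
    return out, converged


def _fit_robust_ml(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
) -> tuple[dict[str, tuple[float, float]], bool]:
    """Marginal ML with a student-t observation model (random intercepts),
    Wald intervals from a finite-difference Hessian."""
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float).copy()
    y = np.asarray(y, dtype=float)
    y_mu, y_sd = y.mean(), y.std() if y.std() > 0 else 1.0
    centers = np.zeros(len(names))
    scales = np.ones(len(names))
    for j, name in enumerate(names):
        col = Xv[:, j]
        if name == "intercept" or set(np.unique(col)) <= {0.0, 1.0}:
            continue
        centers[j], scales[j] = col.mean(), col.std() if col.std() > 0 else 1.0
        Xv[:, j] = (col - centers[j]) / scales[j]
    ys = (y - y_mu) / y_sd
    model = _MarginalLMM(
        ys, Xv, groups, slope_index=None, robust=True,
        prior=PriorSpec(scale=1e6),
    )
    nll = lambda th: -model.log_prob(th)
    x0 = np.concatenate(
        [np.linalg.lstsq(Xv, ys, rcond=None)[0], [np.log(0.5), np.log(0.5)]]
    )
    res = optimize.minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 500})
    if not res.success:
        res = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": 3000, "xatol": 1e-6, "fatol": 1e-8},
        )
    theta = res.x
    # finite-difference Hessian on the full parameter vector
    eps = 1e-4
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = eps, eps
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei) - nll(theta + ej) + nll(theta)
            ) / eps**2
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        ok = bool(res.success) and np.all(np.isfinite(ses[: len(names)]))
    except np.linalg.LinAlgError:
        ses = np.full(k, np.nan)
        ok = False
    out = {}
    for j, name in enumerate(names):
        est = theta[j] * y_sd / scales[j]
        se = ses[j] * y_sd / scales[j]
        out[name] = (float(est), float(se))
    return out, ok


def _estimates_from_fit(
    fit: dict[str, tuple[float, float]],
    terms: list[str],
    n_scans: int,
    n_participants: int,
    method: str,
    converged: bool,
) -> list[GroupEstimate]:
    out = []
    for term in terms:
        est, se = fit[term]
        half = 1.96 * se if np.isfinite(se) else np.nan
        out.append(
            GroupEstimate(
                term=term,
                estimate=est,
                lower=est - half,
                upper=est + half,
                n_scans=n_scans,
                n_participants=n_participants,
                method=method,
                converged=converged,
            )
        )
    return out


def fit_age_model(
    scan_table: pd.DataFrame,
    outcome: str,
    spec: AgeModelSpec = AgeModelSpec(),
    priors: PriorSpec = PriorSpec(),
    seed: int = 0,
    terms_of_interest: list[str] | None = None,
    bayes_kwargs: dict | None = None,
) -> list[GroupEstimate]:
    """Fit ``outcome ~ age_form + mean_fd [+ block + scanner]`` with
    participant random intercepts (and optionally random age slopes).

    Returns one GroupEstimate per age term (other fixed effects can be
    requested via ``terms_of_interest``). Non-convergence is flagged on the
    estimate, never silent.
    """
    df = scan_table.dropna(subset=[outcome]).copy()
    filtered, _ = exclude_outliers(df[outcome], spec.outlier_rule)
    df = df.loc[filtered.index]
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if df[outcome].std() == 0:
        raise ValueError("outcome is degenerate (zero variance)")
    X, terms = _design(df, spec)
    if terms_of_interest is not None:
        terms = terms_of_interest
    y = df[outcome].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    n_scans, n_parts = len(df), df["participant_id"].nunique()
    slope_col = None
    if spec.random_slopes and spec.parametrization == "pooled_age":
        slope_col = "inv_age" if spec.age_form == "inverse" else "age"
    elif spec.random_slopes and spec.parametrization == "within_between":
        slope_col = "age_within"
    if spec.estimation == "bayes_mcmc":
        bres = fit_lmm_bayes(
            y, X, groups,
            slope_col=None if spec.robust else slope_col,
            robust=spec.robust, prior=priors, seed=seed,
            **(bayes_kwargs or {}),
        )
        out = []
        for term in terms:
            med, lo, hi = bres.summary(term)
            out.append(
                GroupEstimate(
                    term=term, estimate=med, lower=lo, upper=hi,
                    n_scans=n_scans, n_participants=n_parts,
                    method="bayes_mcmc", converged=bres.converged,
                )
            )
        return out
    if spec.estimation != "fast_freq":
        raise ValueError(f"unknown estimation: {spec.estimation!r}")
    if spec.robust:
        fit, converged = _fit_robust_ml(y, X, groups)
        method = "fast_freq_robust"
    else:
        fit, converged = _fit_freq_mixedlm(y, X, groups, slope_col)
        method = "fast_freq"
    return _estimates_from_fit(fit, terms, n_scans, n_parts, method, converged)


def fit_within_between(
    scan_table: pd.DataFrame,
    outcome: str,
    spec: AgeModelSpec = AgeModelSpec(),
    seed: int = 0,
) -> dict[str, GroupEstimate]:
    """Within/between age decomposition: participant-mean age (between)
    and deviation from it (within), estimated in one model, plus their
    difference."""
    spec = replace(spec, parametrization="within_between", age_form="linear")
    df = scan_table.dropna(subset=[outcome])
    multi = df.groupby("participant_id")["wave"].count()
    if (multi >= 2).sum() == 0:
        flagged = GroupEstimate(
            term="age_within", estimate=np.nan, lower=np.nan, upper=np.nan,
            n_scans=len(df), n_participants=df["participant_id"].nunique(),
            inestimable=True, reason="no participant has 2+ scans",
        )
        between = fit_age_model(
            scan_table, outcome, replace(spec, parametrization="pooled_age"),
            seed=seed,
        )[0]
        return {
            "age_between": replace_term(between, "age_between"),
            "age_within": flagged,
            "difference": flagged,
        }
    ests = fit_age_model(
        scan_table, outcome, spec, seed=seed,
        terms_of_interest=["age_between", "age_within"],
    )
    by_term = {e.term: e for e in ests}
    # difference of the two slopes, Wald-combined (covariance omitted:
    # between and within regressors are orthogonal by construction)
    eb, ew = by_term["age_between"], by_term["age_within"]
    d = eb.estimate - ew.estimate
    se_d = np.sqrt(
        ((eb.upper - eb.lower) / 3.92) ** 2 + ((ew.upper - ew.lower) / 3.92) ** 2
    )
    by_term["difference"] = GroupEstimate(
        term="difference", estimate=d, lower=d - 1.96 * se_d,
        upper=d + 1.96 * se_d, n_scans=eb.n_scans,
        n_participants=eb.n_participants, method=eb.method,
        converged=eb.converged and ew.converged,
    )
    return by_term


def replace_term(est: GroupEstimate, term: str) -> GroupEstimate:
    from dataclasses import replace as dc_replace

    return dc_replace(est, term=term)


def fit_trial_dynamics_models(
    data: pd.DataFrame,
    variant: str,
    spec: AgeModelSpec = AgeModelSpec(),
    seed: int = 0,
) -> list[GroupEstimate]:
    """Age effects on within-scan reactivity dynamics.

    ``slopes_on_age``: scan-level Spearman slopes regressed on age (same
    multilevel model as reactivity). ``halves_interaction``: first/second
    half mean betas with an age x half interaction and scan-level pairing.
    ``single_trial``: trial-level betas with a trial x age interaction and
    scans nested in participants.
    """
    if variant == "slopes_on_age":
        return fit_age_model(data, "trial_slope", spec, seed=seed)
    df = data.copy()
    df["age_c"] = df["age_at_scan"] - AGE_CENTER
    vc = {"scan": "0 + C(scan_id)"}
    if variant == "halves_interaction":
        df["half2"] = (df["half"] == "second").astype(float)
        formula = "mean_beta ~ age_c * half2 + mean_fd"
        term_label = "age_c:half2"
    elif variant == "single_trial":
        df["trial_c"] = df["trial_index"] - df["trial_index"].mean()
        formula = "beta ~ trial_c * age_c + mean_fd"
        term_label = "trial_c:age_c"
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    df = df.dropna(subset=[formula.split(" ~ ")[0]])
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["participant_id"], vc_formula=vc)
        res = _mixedlm_reml(model)
    converged = bool(getattr(res, "converged", True)) and not any(
        "did not converge" in str(w.message).lower() for w in wlist
    )
    est = float(res.fe_params[term_label])
    se = float(res.bse_fe[term_label])
    return [
        GroupEstimate(
            term="age_x_trial" if variant == "single_trial" else "age_x_half",
            estimate=est, lower=est - 1.96 * se, upper=est + 1.96 * se,
            n_scans=df["scan_id"].nunique(),
            n_participants=df["participant_id"].nunique(),
            method="fast_freq", converged=converged,
        )
    ]


def impute_scared_items(item_table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """k-nearest-neighbor imputation within the item set.

    A missing item is replaced by the mean of that item among the k nearest
    rows by Euclidean distance on the mutually observed standardized items;
    ties broken by row order. If fewer than k candidate rows have the item,
    all available are used.
    """
    items = item_table.to_numpy(dtype=float)
    n, p = items.shape
    mu = np.nanmean(items, axis=0)
    sd = np.nanstd(items, axis=0)
    sd[sd == 0] = 1.0
    z = (items - mu) / sd
    out = items.copy()
    for i in range(n):
        missing = np.isnan(items[i])
        if not missing.any():
            continue
        if not (~missing).any():
            raise ValueError(f"row {i} has no observed items")
        for j in np.where(missing)[0]:
            candidates = np.where(~np.isnan(items[:, j]))[0]
            candidates = candidates[candidates != i]
            if candidates.size == 0:
                out[i, j] = mu[j]
                continue
            dists = np.empty(candidates.size)
            for ci, c in enumerate(candidates):
                both = ~np.isnan(z[i]) & ~np.isnan(z[c])
                both[j] = False
                if not both.any():
                    dists[ci] = np.inf
                else:
                    diff = z[i, both] - z[c, both]
                    dists[ci] = np.sqrt(diff @ diff)
            order = np.argsort(dists, kind="stable")
            nearest = candidates[order[: min(k, candidates.size)]]
            out[i, j] = items[nearest, j].mean()
    return pd.DataFrame(out, index=item_table.index, columns=item_table.columns)


def fit_brain_anxiety_model(
    scan_table: pd.DataFrame,
    brain: str,
    anxiety: str,
    spec: AgeModelSpec = AgeModelSpec(),
    priors: PriorSpec = PriorSpec(),
    seed: int = 0,
    bayes_kwargs: dict | None = None,
) -> GroupEstimate:
    """Standardized anxiety ~ standardized brain measure + age + mean FD
    with participant random intercepts; scans without parent-report scores
    (adults) are dropped."""
    df = scan_table.dropna(subset=[brain, anxiety]).copy()
    df["anxiety_z"] = (df[anxiety] - df[anxiety].mean()) / df[anxiety].std()
    df["brain_z"] = (df[brain] - df[brain].mean()) / df[brain].std()
    X = pd.DataFrame(
        {
            "intercept": np.ones(len(df)),
            "brain_z": df["brain_z"].to_numpy(),
            "age": df["age_at_scan"].to_numpy() - AGE_CENTER,
            "mean_fd": df["mean_fd"].to_numpy(),
        },
        index=df.index,
    )
    y = df["anxiety_z"].to_numpy()
    groups = df["participant_id"].to_numpy()
    if spec.estimation == "bayes_mcmc":
        bres = fit_lmm_bayes(
            y, X, groups, robust=spec.robust, prior=priors, seed=seed,
            **(bayes_kwargs or {}),
        )
        med, lo, hi = bres.summary("brain_z")
        return GroupEstimate(
            term="brain", estimate=med, lower=lo, upper=hi,
            n_scans=len(df), n_participants=df["participant_id"].nunique(),
            method="bayes_mcmc", converged=bres.converged,
        )
    if spec.robust:
        fit, converged = _fit_robust_ml(y, X, groups)
        method = "fast_freq_robust"
    else:
        fit, converged = _fit_freq_mixedlm(y, X, groups, None)
        method = "fast_freq"
    est, se = fit["brain_z"]
    return GroupEstimate(
        term="brain", estimate=est, lower=est - 1.96 * se, upper=est + 1.96 * se,
        n_scans=len(df), n_participants=df["participant_id"].nunique(),
        method=method, converged=converged,
    )
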