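"""Specification grids, multiverse execution, and specification curves.

A grid is a cross-product of factorial decision points, optionally crossed
with a curated list of partial specifications (used where the emulated
study's printed specification counts are not full cross-products of its
decision table; the curated memberships are this package's documented
reconstruction of those counts). Estimates from all forks are ranked into
a specification curve with continuous evidence summaries (proportion of
estimates sharing the median's sign, proportion of 95% intervals excluding
zero by direction), and decision-point meta-regression quantifies the
conditional effect of each analytic choice on the estimate.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_models import AgeModelSpec, fit_age_model
from .simulate import simulate_scan_measures, GenerativeParams
from .cohort import CohortConfig


@dataclass(frozen=True)
class Specification:
    """One analysis fork: a full assignment of decision points to levels."""

    decisions: tuple[tuple[str, str], ...]

    @property
    def fork_id(self) -> str:
        payload = json.dumps(sorted(self.decisions)).encode()
        return hashlib.sha1(payload).hexdigest()[:10]

    def as_dict(self) -> dict[str, str]:
        return dict(self.decisions)

    def __getitem__(self, key: str) -> str:
        return dict(self.decisions)[key]


def enumerate_specs(grid_config: dict) -> list[Specification]:
    """Deterministically enumerate a grid.

    ``grid_config`` has ``factors`` (decision -> list of levels) and an
    optional ``curated`` list of partial decision mappings that is crossed
    with the factorial part.
    """
    factors: dict[str, list] = grid_config.get("factors", {})
    curated: list[dict] = grid_config.get("curated", [{}])
    for decision, levels in factors.items():
        if len(levels) != len(set(map(str, levels))):
            raise ValueError(f"duplicate levels in decision {decision!r}")
        if not levels:
            raise ValueError(f"decision {decision!r} has no levels")
    keys = list(factors)
    specs = []
    for partial in curated:
        for combo in itertools.product(*(factors[k] for k in keys)):
            decisions = dict(partial)
            decisions.update(dict(zip(keys, combo)))
            specs.append(
                Specification(tuple(sorted((k, str(v)) for k, v in decisions.items())))
            )
    ids = [s.fork_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate specifications in grid")
    return specs


# ---------------------------------------------------------------------------
# packaged default grids (counts reproduce the emulated study's printed
# totals; memberships are documented reconstructions)

_GLM_CORE_DEFAULT = {
    "preproc_software": "fsl",
    "glm_software": "fsl",
    "hrf": "double_gamma",
    "nuisance": "24",
    "drift": "highpass_0.01Hz",
}


def _glm_cores() -> list[dict]:
    """13 curated preprocessing/GLM pipeline cores (default plus one-away
    and selected two/three-away variants)."""
    variants = [
        {},
        {"preproc_software": "cpac"},
        {"glm_software": "afni"},
        {"hrf": "single_gamma"},
        {"nuisance": "6"},
        {"nuisance": "18+WM+CSF"},
        {"drift": "quadratic"},
        {"preproc_software": "cpac", "glm_software": "afni"},
        {"preproc_software": "cpac", "nuisance": "6"},
        {"preproc_software": "cpac", "nuisance": "18+WM+CSF"},
        {"preproc_software": "cpac", "drift": "quadratic"},
        {"glm_software": "afni", "hrf": "single_gamma"},
        {"preproc_software": "cpac", "glm_software": "afni", "hrf": "single_gamma"},
    ]
    return [{**_GLM_CORE_DEFAULT, **v} for v in variants]


_GROUP_DEFAULT = {
    "covariates": "mean_fd",
    "outlier": "exclude_3sd",
    "quadratic": "no",
    "random_slopes": "yes",
}

_COV_SETS = ["mean_fd", "mean_fd+block", "mean_fd+scanner", "mean_fd+block+scanner"]


def _group_models_18() -> list[dict]:
    """18 curated group-level model specifications."""
    out = []
    for cov in _COV_SETS:
        for outlier in ["exclude_3sd", "exclude_3sd_plus_robust"]:
            out.append({**_GROUP_DEFAULT, "covariates": cov, "outlier": outlier})
    for cov in _COV_SETS:
        out.append({**_GROUP_DEFAULT, "covariates": cov, "quadratic": "yes"})
    for cov in _COV_SETS:
        out.append({**_GROUP_DEFAULT, "covariates": cov, "random_slopes": "no"})
    for outlier in ["exclude_3sd", "exclude_3sd_plus_robust"]:
        out.append(
            {**_GROUP_DEFAULT, "outlier": outlier, "quadratic": "yes",
             "random_slopes": "no"}
        )
    return out


def _group_models_7() -> list[dict]:
    """7 curated group-level models (trial-dynamics and BSC families)."""
    out = [{**_GROUP_DEFAULT, "covariates": cov} for cov in _COV_SETS]
    out.append({**_GROUP_DEFAULT, "quadratic": "yes"})
    out.append({**_GROUP_DEFAULT, "random_slopes": "no"})
    out.append({**_GROUP_DEFAULT, "outlier": "exclude_3sd_plus_robust"})
    return out


def _cross(curated_a: list[dict], curated_b: list[dict]) -> list[dict]:
    return [{**a, **b} for a in curated_a for b in curated_b]


def default_grid(name: str) -> dict:
    """Packaged default grids for each analysis family."""
    if name == "reactivity":
        # 13 cores x 3 ROIs x 2 estimate types x 2 inclusion = 156
        # participant-level pipelines, x 18 group-level models = 2,808
        return {
            "factors": {
                "amygdala_roi": ["amyg_bilateral", "amyg_left", "amyg_right"],
                "estimate_type": ["beta", "t"],
                "prior_scans": ["include", "exclude"],
            },
            "curated": _cross(_glm_cores(), _group_models_18()),
        }
    if name == "gppi":
        # 4 participant-level gPPI definitions x 4 mPFC ROIs x 18 = 288
        return {
            "factors": {
                "deconvolution": ["yes", "no"],
                "estimate_type": ["beta", "t"],
                "mpfc_roi": ["mpfc1", "mpfc2", "mpfc3", "vmpfc_large"],
            },
            "curated": _group_models_18(),
        }
    if name == "bsc":
        # 3 amygdala x 4 mPFC x 2 global-signal x 7 = 168
        return {
            "factors": {
                "amygdala_roi": ["amyg_bilateral", "amyg_left", "amyg_right"],
                "mpfc_roi": ["mpfc1", "mpfc2", "mpfc3", "vmpfc_large"],
                "gss": ["yes", "no"],
            },
            "curated": _group_models_7(),
        }
    if name == "trial_dynamics":
        # 3 amygdala ROIs x 2 global-signal options x 7 = 42
        return {
            "factors": {
                "amygdala_roi": ["amyg_bilateral", "amyg_left", "amyg_right"],
                "gss": ["yes", "no"],
            },
            "curated": _group_models_7(),
        }
    if name == "anxiety_reactivity":  # 18
        return {
            "factors": {
                "outcome": ["rcads_raw", "scared_raw", "scared_t"],
                "amygdala_roi": ["amyg_bilateral", "amyg_left", "amyg_right"],
                "contrast": ["fear>baseline", "neutral>baseline"],
            }
        }
    if name == "anxiety_gppi":  # 90
        return {
            "factors": {
                "outcome": ["rcads_raw", "scared_raw", "scared_t"],
                "contrast": ["fear>baseline", "neutral>baseline", "fear>neutral"],
                "deconvolution": ["yes", "no"],
                "mpfc_roi": ["mpfc1", "mpfc2", "mpfc3", "vmpfc_large", "mpfc_sphere_avg"],
            }
        }
    if name == "anxiety_bsc":  # 18
        return {
            "factors": {
                "outcome": ["rcads_raw", "scared_raw", "scared_t"],
                "gss": ["yes", "no"],
                "mpfc_roi": ["mpfc1", "mpfc2", "mpfc3"],
            }
        }
    if name == "anxiety_slopes":  # 12
        return {
            "factors": {
                "outcome": ["rcads_raw", "scared_raw", "scared_t"],
                "gss": ["yes", "no"],
                "condition": ["fear", "neutral"],
            }
        }
    if name == "reactivity_reduced":
        # 24-spec grid for calibration studies (amplitude-level measures);
        # random-intercept models only, so a calibration sweep stays cheap
        return {
            "factors": {
                "amygdala_roi": ["amyg_bilateral", "amyg_left", "amyg_right"],
                "covariates": _COV_SETS,
                "quadratic": ["yes", "no"],
            },
            "curated": [{"random_slopes": "no"}],
        }
    raise ValueError(f"unknown grid: {name!r}")


# ---------------------------------------------------------------------------
# execution


def run_multiverse(
    specs: list[Specification],
    executor,
    existing: pd.DataFrame | None = None,
    max_failure_fraction: float = 0.2,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run ``executor(spec) -> GroupEstimate`` over every specification.

    Per-spec failures are logged (error class and message) without aborting
    the sweep; more than ``max_failure_fraction`` failures raises. A
    previous estimates table can be passed to resume by fork-id, and
    ``n_jobs`` enables local parallelism over specifications.
    """
    done = set(existing["fork_id"]) if existing is not None else set()
    todo = [s for s in specs if s.fork_id not in done]

    def _one(spec: Specification):
        try:
            return spec, executor(spec), None
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            return spec, None, exc

    if n_jobs == 1:
        outcomes = [_one(s) for s in todo]
    else:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=n_jobs)(delayed(_one)(s) for s in todo)
    rows, failures = [], []
    for spec, est, exc in outcomes:
        if exc is not None:
            failures.append(
                {
                    "fork_id": spec.fork_id,
                    "error": type(exc).__name__,
                    "message": str(exc),
                }
            )
            continue
        row = dict(spec.decisions)
        row.update(
            {
                "fork_id": spec.fork_id,
                "term": est.term,
                "estimate": est.estimate,
                "lower": est.lower,
                "upper": est.upper,
                "excludes_zero": est.excludes_zero,
                "sign": est.sign,
                "converged": est.converged,
            }
        )
        rows.append(row)
    if len(specs) and len(failures) > max_failure_fraction * len(specs):
        raise RuntimeError(
            f"{len(failures)}/{len(specs)} specifications failed; "
            "sweep aborted (failure fraction above threshold)"
        )
    table = pd.DataFrame(rows)
    if existing is not None and len(existing):
        table = pd.concat([existing, table], ignore_index=True)
    return table, failures


@dataclass
class SpecCurve:
    """Ranked estimates plus continuous evidence summaries."""

    table: pd.DataFrame = field(repr=False)  # sorted ascending by estimate
    median: float = np.nan
    prop_same_sign: float = np.nan
    prop_excluding_zero: dict = field(default_factory=dict)
    rank_summary: pd.DataFrame | None = field(default=None, repr=False)


def build_spec_curve(
    estimates: pd.DataFrame,
    term: str | None = None,
    decision_columns: list[str] | None = None,
) -> SpecCurve:
    """Rank specifications by estimate (ascending) and summarize evidence.

    The same-sign proportion is referenced to the sign of the median
    estimate; interval-evidence proportions are reported by direction.
    Decision-level rank summaries give the median and IQR of curve ranks
    for every level of every decision point.
    """
    df = estimates.copy()
    if term is not None and "term" in df.columns:
        df = df[df["term"] == term]
    if df.empty:
        raise ValueError("no estimates to build a curve from")
    df = df.sort_values("estimate", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    median = float(df["estimate"].median())
    med_sign = np.sign(median) if median != 0 else 1.0
    prop_same = float((np.sign(df["estimate"]) == med_sign).mean())
    excl = df["excludes_zero"].astype(bool)
    props = {
        "negative": float((excl & (df["estimate"] < 0)).mean()),
        "positive": float((excl & (df["estimate"] > 0)).mean()),
        "same_direction_as_median": float(
            (excl & (np.sign(df["estimate"]) == med_sign)).mean()
        ),
    }
    if decision_columns is None:
        reserved = {
            "fork_id", "term", "estimate", "lower", "upper", "excludes_zero",
            "sign", "rank", "converged",
        }
        decision_columns = [c for c in df.columns if c not in reserved]
    summaries = []
    for col in decision_columns:
        for level, grp in df.groupby(col):
            ranks = grp["rank"]
            summaries.append(
                {
                    "decision": col,
                    "level": level,
                    "median_rank": float(ranks.median()),
                    "iqr_low": float(ranks.quantile(0.25)),
                    "iqr_high": float(ranks.quantile(0.75)),
                    "n": len(grp),
                }
            )
    rank_summary = (
        pd.DataFrame(summaries).sort_values(["decision", "median_rank"]).reset_index(
            drop=True
        )
        if summaries
        else None
    )
    return SpecCurve(
        table=df,
        median=median,
        prop_same_sign=prop_same,
        prop_excluding_zero=props,
        rank_summary=rank_summary,
    )


def decision_effects(
    estimates: pd.DataFrame,
    decision_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Conditional effect of each analysis choice on the point estimate.

    Linear regression of estimates on indicator-coded decision levels
    (reference level = first level in sorted order, noted per decision).
    Fully aliased decision pairs raise with the alias named.
    """
    df = estimates.copy()
    if decision_columns is None:
        reserved = {
            "fork_id", "term", "estimate", "lower", "upper", "excludes_zero",
            "sign", "rank", "converged",
        }
        decision_columns = [
            c for c in df.columns if c not in reserved and df[c].nunique() > 1
        ]
    if len(decision_columns) < 2:
        raise ValueError("need at least 2 varying decision points")
    for a, b in itertools.combinations(decision_columns, 2):
        if (df.groupby(a)[b].nunique() == 1).all() and (
            df.groupby(b)[a].nunique() == 1
        ).all():
            raise ValueError(f"decisions {a!r} and {b!r} are fully aliased")
    dummies = []
    meta = []
    for col in decision_columns:
        levels = sorted(df[col].astype(str).unique())
        for level in levels[1:]:
            dummies.append((df[col].astype(str) == level).astype(float).rename(
                f"{col}={level}"
            ))
            meta.append({"decision": col, "level": level, "reference": levels[0]})
    X = pd.concat([pd.Series(1.0, index=df.index, name="intercept")] + dummies, axis=1)
    Xv = X.to_numpy()
    y = df["estimate"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ coef
    dof = max(len(y) - Xv.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(Xv.T @ Xv)
    ses = np.sqrt(np.diag(cov))
    rows = []
    for i, m in enumerate(meta, start=1):
        rows.append(
            {
                **m,
                "coef": float(coef[i]),
                "se": float(ses[i]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration studies on the reduced grid


def _measures_executor(measures: pd.DataFrame, spec: Specification):
    d = spec.as_dict()
    outcome = f"reactivity_{d.get('amygdala_roi', 'amyg_bilateral')}"
    model_spec = AgeModelSpec(
        covariates=d.get("covariates", "mean_fd"),
        random_slopes=d.get("random_slopes", "yes") == "yes",
        age_form="quadratic" if d.get("quadratic", "no") == "yes" else "linear",
        outlier_rule=d.get("outlier", "exclude_3sd"),
        robust=d.get("outlier", "") == "exclude_3sd_plus_robust",
        estimation="fast_freq",
    )
    return fit_age_model(measures, outcome, model_spec)[0]


def run_reduced_reactivity(
    measures: pd.DataFrame, specs: list[Specification] | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the reduced reactivity grid on amplitude-level scan measures."""
    if specs is None:
        specs = enumerate_specs(default_grid("reactivity_reduced"))
    return run_multiverse(specs, lambda s: _measures_executor(measures, s))


def null_calibration(
    n_cohorts: int = 100,
    seed: int = 0,
    params: GenerativeParams | None = None,
    config: CohortConfig | None = None,
) -> dict:
    """Calibration of curve summaries under a zero-effect generative model.

    Pools reduced-grid estimates across independent null cohorts; reports
    the mean proportion of 95% intervals excluding zero (nominal ~0.05) and
    the pooled proportion of estimates sharing the pooled median's sign
    (~0.5: under the null the median's sign carries no information).
    """
    rng = np.random.default_rng(seed)
    params = (params or GenerativeParams()).null()
    config = config or CohortConfig()
    specs = enumerate_specs(default_grid("reactivity_reduced"))
    all_est: list[pd.DataFrame] = []
    for _ in range(n_cohorts):
        measures = simulate_scan_measures(
            config, params, seed=int(rng.integers(2**31))
        )
        table, _ = run_reduced_reactivity(measures, specs)
        all_est.append(table)
    pooled = pd.concat(all_est, ignore_index=True)
    med = pooled["estimate"].median()
    med_sign = np.sign(med) if med != 0 else 1.0
    return {
        "excludes_zero_rate": float(pooled["excludes_zero"].mean()),
        "same_sign_pooled": float((np.sign(pooled["estimate"]) == med_sign).mean()),
        "n_estimates": int(len(pooled)),
        "n_cohorts": n_cohorts,
    }
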