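"""Bayesian linear mixed models via ensemble MCMC on the marginal likelihood.

The group-level models are Gaussian (or, for the robust fork, student-t)
regressions with participant random intercepts and optionally a random age
slope. Random effects are integrated out analytically (Gaussian likelihood,
Woodbury identity on the per-group marginal covariance) or by Gauss-Hermite
quadrature (t likelihood, random intercepts), and the resulting marginal
posterior over fixed effects and variance parameters is sampled with an
affine-invariant ensemble sampler (emcee). Fixed-effect priors are weakly
informative student-t(3, 0, 10) on standardized units; scale parameters get
half-t(3, 0, 2.5) priors. Outcome and continuous predictors are
standardized internally and draws are mapped back to the original scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss

_HALF_T_SCALE = 2.5
_ROBUST_DF = 4.0  # fixed student-t df of the robust observation model
_GH_NODES = 21


@dataclass(frozen=True)
class PriorSpec:
    """Student-t prior on standardized fixed effects."""

    df: float = 3.0
    location: float = 0.0
    scale: float = 10.0


@dataclass
class BayesResult:
    draws: pd.DataFrame  # one column per parameter, original scale
    converged: bool
    rhat: dict[str, float] = field(default_factory=dict)

    def summary(self, term: str) -> tuple[float, float, float]:
        """Posterior median and central 95% interval for one term."""
        d = self.draws[term].to_numpy()
        return (
            float(np.median(d)),
            float(np.quantile(d, 0.025)),
            float(np.quantile(d, 0.975)),
        )


def _t_logpdf(z: np.ndarray, df: float) -> np.ndarray:
    return (
        math.lgamma((df + 1) / 2)
        - math.lgamma(df / 2)
        - 0.5 * math.log(df * math.pi)
        - (df + 1) / 2 * np.log1p(z**2 / df)
    )


class _MarginalLMM:
    """Marginal log-posterior of the mixed model on standardized data.

    Parameter vector: beta (p), log sigma, log tau0 [, log tau1, atanh(rho)]
    for a random slope on one column of X.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        groups: np.ndarray,
        slope_index: int | None = None,
        robust: bool = False,
        prior: PriorSpec = PriorSpec(),
    ) -> None:
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = np.asarray(groups)[order]
        _, self.starts = np.unique(g, return_index=True)
        self.n_g = np.diff(np.append(self.starts, len(g)))
        self.slope_index = slope_index
        self.robust = robust
        if robust and slope_index is not None:
            raise NotImplementedError(
                "robust Bayesian fits support random intercepts only"
            )
        self.prior = prior
        self.p = X.shape[1]
        self.ndim = self.p + 2 + (2 if slope_index is not None else 0)
        if slope_index is not None:
            x = self.X[:, slope_index]
            self.Sx = np.add.reduceat(x, self.starts)
            self.Sxx = np.add.reduceat(x * x, self.starts)
            self.xcol = x
        if robust:
            nodes, weights = hermgauss(_GH_NODES)
            self.gh_nodes = nodes
            self.gh_logw = np.log(weights) - 0.5 * math.log(math.pi)

    # ---- likelihood pieces -------------------------------------------------

    def _gaussian_loglik(self, r: np.ndarray, sigma: float, tau0: float,
                         tau1: float = 0.0, rho: float = 0.0) -> float:
        s2 = sigma**2
        S1 = np.add.reduceat(r, self.starts)
        S2 = np.add.reduceat(r * r, self.starts)
        if self.slope_index is None:
            t2 = tau0**2
            prec = 1.0 / t2 + self.n_g / s2
            quad = S2 / s2 - (S1 / s2) ** 2 / prec
            logdet = self.n_g * math.log(s2) + math.log(t2) + np.log(prec)
            return float(
                -0.5 * np.sum(quad + logdet + self.n_g * math.log(2 * math.pi))
            )
        # random intercept + slope: G = [[t0^2, c],[c, t1^2]], c = rho t0 t1
        Sxr = np.add.reduceat(self.xcol * r, self.starts)
        t0sq, t1sq = tau0**2, tau1**2
        c = rho * tau0 * tau1
        detG = t0sq * t1sq - c**2
        if detG <= 1e-12:
            return -np.inf
        # Ginv
        gi00, gi11, gi01 = t1sq / detG, t0sq / detG, -c / detG
        m00 = gi00 + self.n_g / s2
        m01 = gi01 + self.Sx / s2
        m11 = gi11 + self.Sxx / s2
        detM = m00 * m11 - m01**2
        if np.any(detM <= 0):
            return -np.inf
        u0, u1 = S1 / s2, Sxr / s2
        quad = S2 / s2 - (m11 * u0**2 - 2 * m01 * u0 * u1 + m00 * u1**2) / detM
        logdet = self.n_g * math.log(s2) + math.log(detG) + np.log(detM)
        return float(
            -0.5 * np.sum(quad + logdet + self.n_g * math.log(2 * math.pi))
        )

    def _robust_loglik(self, r: np.ndarray, sigma: float, tau0: float) -> float:
        b = math.sqrt(2.0) * tau0 * self.gh_nodes  # (K,)
        z = (r[:, None] - b[None, :]) / sigma  # (N, K)
        lp = _t_logpdf(z, _ROBUST_DF) - math.log(sigma)
        per_group = np.add.reduceat(lp, self.starts, axis=0)  # (G, K)
        m = per_group.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(
            np.exp(per_group - m) @ np.exp(self.gh_logw)
        )
        return float(np.sum(lse))

    # ---- posterior ---------------------------------------------------------

    def log_prob(self, theta: np.ndarray) -> float:
        beta = theta[: self.p]
        log_sigma, log_tau0 = theta[self.p], theta[self.p + 1]
        if abs(log_sigma) > 10 or abs(log_tau0) > 10:
            return -np.inf
        sigma, tau0 = math.exp(log_sigma), math.exp(log_tau0)
        tau1, rho = 0.0, 0.0
        if self.slope_index is not None:
            log_tau1, arho = theta[self.p + 2], theta[self.p + 3]
            if abs(log_tau1) > 10 or abs(arho) > 5:
                return -np.inf
            tau1, rho = math.exp(log_tau1), math.tanh(arho)
        r = self.y - self.X @ beta
        if self.robust:
            ll = self._robust_loglik(r, sigma, tau0)
        else:
            ll = self._gaussian_loglik(r, sigma, tau0, tau1, rho)
        # priors: student-t on beta; half-t on scales (plus log-Jacobian)
        pr = float(
            np.sum(_t_logpdf((beta - self.prior.location) / self.prior.scale,
                             self.prior.df))
        )
        for s, log_s in ((sigma, log_sigma), (tau0, log_tau0)):
            pr += float(_t_logpdf(np.array(s / _HALF_T_SCALE), 3.0)) + log_s
        if self.slope_index is not None:
            pr += float(_t_logpdf(np.array(tau1 / _HALF_T_SCALE), 3.0)) + math.log(
                tau1
            )
        return ll + pr


def _split_rhat(chains: np.ndarray) -> float:
    """Potential scale reduction across walkers (split in half along steps)."""
    n_steps, n_walkers = chains.shape
    half = n_steps // 2
    segs = np.concatenate([chains[:half], chains[half : 2 * half]], axis=1)
    m = segs.shape[1]
    n = segs.shape[0]
    means = segs.mean(axis=0)
    B = n * means.var(ddof=1)
    W = segs.var(axis=0, ddof=1).mean()
    if W <= 0:
        return np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def fit_lmm_bayes(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    slope_col: str | None = None,
    robust: bool = False,
    prior: PriorSpec = PriorSpec(),
    seed: int = 0,
    n_steps: int = 700,
    n_burn: int = 250,
    rhat_threshold: float = 1.05,
) -> BayesResult:
    """Sample the mixed-model posterior.

    ``X`` must contain an ``intercept`` column; continuous columns are
    standardized internally. Returns draws on the original scale for every
    fixed effect plus ``sigma`` and ``tau_participant``.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float).copy()
    y_mu, y_sd = y.mean(), y.std()
    y_sd = y_sd if y_sd > 0 else 1.0
    scales = np.ones(len(names))
    centers = np.zeros(len(names))
    for j, name in enumerate(names):
        col = Xv[:, j]
        if name == "intercept" or set(np.unique(col)) <= {0.0, 1.0}:
            continue
        centers[j], scales[j] = col.mean(), col.std() if col.std() > 0 else 1.0
        Xv[:, j] = (col - centers[j]) / scales[j]
    ys = (y - y_mu) / y_sd
    slope_index = names.index(slope_col) if slope_col is not None else None
    model = _MarginalLMM(ys, Xv, groups, slope_index, robust, prior)
    rng = np.random.default_rng(seed)
    ndim = model.ndim
    n_walkers = max(2 * ndim + 2, 16)
    # start near a ridge-ish OLS solution with jitter
    beta0 = np.linalg.lstsq(Xv, ys, rcond=None)[0]
    center = np.concatenate(
        [beta0, [math.log(0.5), math.log(0.5)]]
        + ([[math.log(0.3), 0.0]] if slope_index is not None else [])
    )
    p0 = center[None, :] + 0.05 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, model.log_prob)
    sampler.random_state = np.random.RandomState(seed % 2**31).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain()  # (steps, walkers, ndim)
    kept = chain[n_burn:]
    rhat = {}
    for j, name in enumerate(names):
        rhat[name] = _split_rhat(kept[:, :, j])
    converged = all(v < rhat_threshold for v in rhat.values())
    flat = kept.reshape(-1, ndim)
    draws = {}
    for j, name in enumerate(names):
        b = flat[:, j] * y_sd / scales[j]
        if name == "intercept":
            # un-center: intercept absorbs the centering of the others
            adj = np.zeros(flat.shape[0])
            for k, nm in enumerate(names):
                if nm != "intercept" and centers[k] != 0:
                    adj += flat[:, k] * y_sd / scales[k] * centers[k]
            b = flat[:, j] * y_sd + y_mu - adj
        draws[name] = b
    draws["sigma"] = np.exp(flat[:, model.p]) * y_sd
    draws["tau_participant"] = np.exp(flat[:, model.p + 1]) * y_sd
    return BayesResult(draws=pd.DataFrame(draws), converged=converged, rhat=rhat)
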