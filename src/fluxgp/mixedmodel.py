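"""Single-kernel REML mixed model and GBLUP.

The model is ``y = 1 mu + u + e`` with ``u ~ N(0, K sigma2_u)`` and
``e ~ N(0, I sigma2_e)``.  Variance components maximize the restricted
likelihood; with the spectral decomposition K = Q L Q' the problem reduces
to a one-dimensional search over the variance ratio lambda = sigma2_u /
sigma2_e, scanned on a log grid and refined by golden section.  The same
fit is reused three ways downstream: GBLUP of phenotypes, per-reaction
rough estimates of flux location/variances, and per-reaction flux
prediction inside the predict-then-project baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import FluxTable, Kinship

__all__ = ["VarianceFit", "GeneticParams", "reml_single_kernel", "gblup_predict", "estimate_reaction_params"]

_VAR_FLOOR_REL = 1e-8  # variance floor, in units of var(y)
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceFit:
    """REML solution for one response vector."""

    mu: float
    sigma2_u: float
    sigma2_e: float
    loglik: float          # restricted log-likelihood at the optimum
    blups: np.ndarray      # genetic BLUPs for the training genotypes
    alpha: np.ndarray      # (sigma2_u K + sigma2_e I)^-1 (y - 1 mu)
    train_idx: np.ndarray | None = None


@dataclass
class GeneticParams:
    """Per-reaction location and variance components (flux units)."""

    mu: np.ndarray
    sigma2_u: np.ndarray
    sigma2_v: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2_u = np.asarray(self.sigma2_u, dtype=float)
        self.sigma2_v = np.asarray(self.sigma2_v, dtype=float)
        if not (len(self.mu) == len(self.sigma2_u) == len(self.sigma2_v)):
            raise ValueError("per-reaction parameter arrays differ in length")
        if (self.sigma2_u < 0).any() or (self.sigma2_v < 0).any():
            raise ValueError("variance components must be nonnegative")

    @property
    def n_reactions(self) -> int:
        return len(self.mu)


def restricted_loglik(y: np.ndarray, k: np.ndarray, sigma2_u: float, sigma2_e: float) -> float:
    """Restricted log-likelihood of (sigma2_u, sigma2_e) for y = 1 mu + u + e.

    Direct (non-profiled) evaluation; used both by the optimizer's oracle
    tests and as the value reported in :class:`VarianceFit`.
    """
    n = len(y)
    v = sigma2_u * k + sigma2_e * np.eye(n)
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0:
        return -np.inf
    vi = np.linalg.solve(v, np.eye(n))
    one = np.ones(n)
    xvx = one @ vi @ one
    mu = (one @ vi @ y) / xvx
    r = y - mu
    return -0.5 * (logdet + np.log(xvx) + r @ vi @ r + (n - 1) * _LOG2PI)


def _profile(lam: float, lam_ev: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> tuple[float, float, float]:
    """Profiled REML criterion at variance ratio lam; returns (ll, mu, s2e)."""
    n = len(yt)
    d = lam * lam_ev + 1.0
    xdx = float(np.sum(xt * xt / d))
    mu = float(np.sum(xt * yt / d)) / xdx
    r = yt - mu * xt
    s2e = float(np.sum(r * r / d)) / (n - 1)
    if s2e <= 0 or not np.isfinite(s2e):
        return -np.inf, mu, max(s2e, 0.0)
    ll = -0.5 * (
        (n - 1) * (np.log(s2e) + 1.0 + _LOG2PI) + float(np.sum(np.log(d))) + np.log(xdx)
    )
    return ll, mu, s2e


def reml_single_kernel(y: np.ndarray, kinship: Kinship | np.ndarray) -> VarianceFit:
    """Fit ``y = 1 mu + u + e`` by REML over the training genotypes.

    ``kinship`` must already be restricted to the genotypes of ``y``.
    """
    y = np.asarray(y, dtype=float)
    k = kinship.values if isinstance(kinship, Kinship) else np.asarray(kinship, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("REML needs at least 3 observations")
    if k.shape != (n, n):
        raise ValueError(f"kinship shape {k.shape} does not match {n} observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    vary = float(np.var(y, ddof=1))
    floor = _VAR_FLOOR_REL * (vary if vary > 0 else 1.0)
    if vary <= 0.0:
        # constant response: boundary case, no variance to partition
        return VarianceFit(
            mu=float(y[0]), sigma2_u=floor, sigma2_e=floor,
            loglik=restricted_loglik(y, k, floor, floor),
            blups=np.zeros(n), alpha=np.zeros(n),
        )

    ev, q = np.linalg.eigh(k)
    ev = np.clip(ev, 0.0, None)
    yt = q.T @ y
    xt = q.T @ np.ones(n)

    grid = np.concatenate(([0.0], np.exp(np.linspace(np.log(1e-8), np.log(1e8), 65))))
    lls = np.array([_profile(l, ev, yt, xt)[0] for l in grid])
    best = int(np.argmax(lls))
    lo = grid[best - 1] if best > 0 else 0.0
    hi = grid[best + 1] if best + 1 < len(grid) else grid[best] * 100.0
    res = minimize_scalar(
        lambda l: -_profile(l, ev, yt, xt)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * max(hi, 1.0), "maxiter": 500},
    )
    lam = float(res.x) if -res.fun >= lls[best] else float(grid[best])
    ll, mu, s2e = _profile(lam, ev, yt, xt)
    if not np.isfinite(ll):
        raise RuntimeError("REML optimization produced a non-finite likelihood")
    s2u = max(lam * s2e, 0.0)
    s2e = max(s2e, floor)
    # BLUP system solved with the reported (floored) components so that the
    # returned pieces are mutually consistent even at the boundary
    alpha = np.linalg.solve(s2u * k + s2e * np.eye(n), y - mu)
    blups = s2u * (k @ alpha)
    return VarianceFit(
        mu=float(mu), sigma2_u=float(s2u), sigma2_e=float(s2e),
        loglik=float(restricted_loglik(y, k, s2u, s2e)),
        blups=blups, alpha=alpha,
    )


def gblup_predict(
    fit: VarianceFit,
    kinship: Kinship | np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """GBLUP predictions for test genotypes.

    ``yhat_test = mu + sigma2_u K[test, train] alpha`` with ``alpha``
    solved on the training block during :func:`reml_single_kernel`.
    """
    k = kinship.values if isinstance(kinship, Kinship) else np.asarray(kinship, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets overlap")
    if len(train_idx) != len(fit.alpha):
        raise ValueError("fit was not produced on this training set")
    return fit.mu + fit.sigma2_u * (k[np.ix_(test_idx, train_idx)] @ fit.alpha)


def estimate_reaction_params(flux_table: FluxTable, kinship: Kinship | np.ndarray) -> GeneticParams:
    """Rough per-reaction (mu, sigma2_U, sigma2_V) from training fluxes.

    One REML fit of ``V_j = 1 mu_j + U_j + r_j`` per reaction.  Reactions
    whose fit fails (or whose fluxes are constant) fall back to the sample
    mean and an even split of the (floored) sample variance — downstream
    only rough magnitudes are needed.
    """
    v = flux_table.values
    n, j_total = v.shape
    mu = np.empty(j_total)
    s2u = np.empty(j_total)
    s2v = np.empty(j_total)
    for j in range(j_total):
        yj = v[:, j]
        vary = float(np.var(yj, ddof=1)) if n > 1 else 0.0
        floor = _VAR_FLOOR_REL * (vary if vary > 0 else 1.0)
        try:
            if vary <= 0.0:
                raise ValueError("constant flux")
            fit = reml_single_kernel(yj, kinship)
            mu[j] = fit.mu
            s2u[j] = max(fit.sigma2_u, floor)
            s2v[j] = max(fit.sigma2_e, floor)
        except (ValueError, RuntimeError):
            mu[j] = float(np.mean(yj))
            s2u[j] = s2v[j] = max(vary / 2.0, floor)
    return GeneticParams(mu=mu, sigma2_u=s2u, sigma2_v=s2v)
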