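"""No-U-Turn sampler with dual-averaging step-size and diagonal mass
adaptation.

A compact, dependency-free implementation of the slice-variable NUTS tree
(Hoffman & Gelman 2014, Alg. 6) over a user-supplied ``logp_and_grad``
callable on an unconstrained parameter vector.  Warmup runs in three
phases: an initial step-size-only phase, a mass-estimation window whose
sample variances become the new diagonal metric (with the step size then
re-found and dual averaging restarted), and a final step-size-only phase.
Deterministic given the ``numpy`` Generator passed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_MAX_DELTA_H = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_kept, dim) post-warmup draws
    logp: np.ndarray           # (n_kept,) log posterior at each draw
    step_size: float
    inv_mass: np.ndarray       # final diagonal inverse metric
    divergences: int           # post-warmup divergent trajectories
    mean_accept: float         # post-warmup mean acceptance statistic
    treedepths: np.ndarray


class _Tree:
    __slots__ = ("theta_m", "r_m", "g_m", "theta_p", "r_p", "g_p",
                 "theta_prop", "logp_prop", "n", "stop", "alpha", "n_alpha", "diverged")


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * (inv_mass * r1)
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp1, grad1


def _joint(logp, r, inv_mass):
    return logp - 0.5 * float(np.sum(r * r * inv_mass))


def _find_step_size(logp_grad, theta, logp, grad, inv_mass, rng):
    eps = 1.0
    r0 = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = _joint(logp, r0, inv_mass)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r0, grad, eps, inv_mass)
    h1 = _joint(logp1, r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0 ** direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r0, grad, eps, inv_mass)
        h1 = _joint(logp1, r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-10)


def _build_tree(logp_grad, theta, r, grad, log_u, direction, depth, eps, inv_mass, h0, rng):
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(logp_grad, theta, r, grad, direction * eps, inv_mass)
        h1 = _joint(logp1, r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        t = _Tree()
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.r_m = t.r_p = r1
        t.g_m = t.g_p = grad1
        t.logp_prop = logp1
        t.n = 1 if log_u <= h1 else 0
        t.diverged = (h1 - h0) < -_MAX_DELTA_H or log_u - _MAX_DELTA_H > h1
        t.stop = t.diverged
        t.alpha = min(1.0, float(np.exp(min(h1 - h0, 0.0))))
        t.n_alpha = 1
        return t
    t = _build_tree(logp_grad, theta, r, grad, log_u, direction, depth - 1, eps, inv_mass, h0, rng)
    if not t.stop:
        if direction == -1:
            t2 = _build_tree(logp_grad, t.theta_m, t.r_m, t.g_m, log_u, direction,
                             depth - 1, eps, inv_mass, h0, rng)
            t.theta_m, t.r_m, t.g_m = t2.theta_m, t2.r_m, t2.g_m
        else:
            t2 = _build_tree(logp_grad, t.theta_p, t.r_p, t.g_p, log_u, direction,
                             depth - 1, eps, inv_mass, h0, rng)
            t.theta_p, t.r_p, t.g_p = t2.theta_p, t2.r_p, t2.g_p
        total = t.n + t2.n
        if t2.n > 0 and rng.random() < t2.n / max(total, 1):
            t.theta_prop, t.logp_prop = t2.theta_prop, t2.logp_prop
        dtheta = t.theta_p - t.theta_m
        no_uturn = (float(dtheta @ (inv_mass * t.r_m)) >= 0.0
                    and float(dtheta @ (inv_mass * t.r_p)) >= 0.0)
        t.stop = t2.stop or not no_uturn
        t.diverged = t.diverged or t2.diverged
        t.n = total
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
    return t


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_iterations: int,
    warmup: int,
    rng: np.random.Generator,
    thinning: int = 1,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws (thinned)."""
    with np.errstate(over="ignore", invalid="ignore"):
        return _nuts_sample(logp_grad, theta0, n_iterations, warmup, rng,
                            thinning, max_treedepth, target_accept)


def _nuts_sample(logp_grad, theta0, n_iterations, warmup, rng,
                 thinning, max_treedepth, target_accept) -> NutsResult:
    theta = np.array(theta0, dtype=float)
    dim = len(theta)
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("log posterior is not finite at the initial point")
    inv_mass = np.ones(dim)

    # Stan-style warmup: an initial step-size-only buffer, doubling
    # mass-estimation windows, and a terminal step-size-only buffer
    init_buf = max(int(0.15 * warmup), 5)
    term_buf = max(int(0.1 * warmup), 5)
    end_adapt = max(warmup - term_buf, init_buf + 1)
    window_ends: list[int] = []
    pos = init_buf
    size = 25 if warmup >= 150 else max(5, warmup // 10)
    while pos < end_adapt:
        nxt = min(pos + size, end_adapt)
        if end_adapt - nxt < 2 * size:
            nxt = end_adapt
        window_ends.append(nxt)
        pos = nxt
        size *= 2

    eps = _find_step_size(logp_grad, theta, logp, grad, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0
    window: list[np.ndarray] = []

    kept: list[np.ndarray] = []
    kept_logp: list[float] = []
    depths: list[int] = []
    divergences = 0
    accepts: list[float] = []

    for it in range(n_iterations):
        in_warmup = it < warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = _joint(logp, r0, inv_mass)
        log_u = h0 + np.log(rng.random())
        theta_m = theta_p = theta
        r_m = r_p = r0
        g_m = g_p = grad
        theta_new, logp_new = theta, logp
        n_total = 1
        stop = False
        diverged = False
        depth = 0
        alpha_sum, n_alpha = 0.0, 0
        while not stop and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                t = _build_tree(logp_grad, theta_m, r_m, g_m, log_u, -1, depth, eps, inv_mass, h0, rng)
                theta_m, r_m, g_m = t.theta_m, t.r_m, t.g_m
            else:
                t = _build_tree(logp_grad, theta_p, r_p, g_p, log_u, 1, depth, eps, inv_mass, h0, rng)
                theta_p, r_p, g_p = t.theta_p, t.r_p, t.g_p
            if not t.stop and t.n > 0 and rng.random() < min(1.0, t.n / n_total):
                theta_new, logp_new = t.theta_prop, t.logp_prop
            n_total += t.n
            alpha_sum += t.alpha
            n_alpha += t.n_alpha
            diverged = diverged or t.diverged
            dtheta = theta_p - theta_m
            no_uturn = (float(dtheta @ (inv_mass * r_m)) >= 0.0
                        and float(dtheta @ (inv_mass * r_p)) >= 0.0)
            stop = t.stop or not no_uturn
            depth += 1
        theta, logp = theta_new, logp_new
        _, grad = logp_grad(theta)
        accept_stat = alpha_sum / max(n_alpha, 1)

        if in_warmup:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * h_bar
            w_ = adapt_count ** (-kappa)
            log_eps_bar = w_ * log_eps + (1.0 - w_) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= init_buf:
                window.append(theta.copy())
            if window_ends and it == window_ends[0] - 1:
                window_ends.pop(0)
                if len(window) >= 10:
                    var = np.var(np.asarray(window), axis=0)
                    nw = len(window)
                    # regularized toward a small unit metric, as in Stan
                    inv_mass = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * 1e-3
                    inv_mass = np.clip(inv_mass, 1e-10, 1e10)
                    eps = _find_step_size(logp_grad, theta, logp, grad, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
                window = []
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar)) if adapt_count > 0 else eps
        else:
            divergences += int(diverged)
            accepts.append(accept_stat)
            depths.append(depth)
            if (it - warmup) % thinning == 0:
                kept.append(theta.copy())
                kept_logp.append(logp)

    return NutsResult(
        draws=np.asarray(kept),
        logp=np.asarray(kept_logp),
        step_size=eps,
        inv_mass=inv_mass,
        divergences=divergences,
        mean_accept=float(np.mean(accepts)) if accepts else float("nan"),
        treedepths=np.asarray(depths),
    )
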