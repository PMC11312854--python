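"""Fitting the constrained flux model by NUTS and summarizing posteriors."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Dataset
from .model import FluxBalanceModel, ModelConfig
from .nuts import nuts_sample
from .scaling import ScalingParams

__all__ = ["PosteriorSamples", "fit_model", "predict_phenotypes", "convergence_report"]

RHAT_THRESHOLD = 1.1


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus sampler metadata.

    Scalar/vector draws have shape (n_draws,) or (n_draws, J); the flux and
    genetic-value draws have shape (n_draws, N, J) on the standardized
    scale.  ``n_draws = chains * (iterations - warmup) / thinning``.
    """

    a: np.ndarray
    b: np.ndarray
    sigma2_e: np.ndarray
    sigma2_eps: np.ndarray
    s_eps: np.ndarray
    sigma2_v: np.ndarray
    sigma2_u: np.ndarray
    u: np.ndarray
    v: np.ndarray
    logp: np.ndarray
    scaling: ScalingParams
    config: ModelConfig
    target_index: int
    chains: int = 1
    divergences: int = 0
    seed: int = 0
    runtime_s: float = 0.0
    sampler_info: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.a)


def fit_model(
    dataset: Dataset,
    train_mask: np.ndarray,
    scaling: ScalingParams,
    config: ModelConfig,
    init_fluxes: np.ndarray | None = None,
) -> PosteriorSamples:
    """Sample the joint posterior with NUTS.

    ``scaling`` must come from training-only rough estimates.  In
    simulation-fitting mode (``config.simulation_jitter``) a pre-drawn
    jitter with variance ``config.psi_variance`` is added to the constraint
    left-hand side.  ``init_fluxes`` optionally supplies standardized
    starting fluxes (NaN entries fall back to the default start).
    """
    t0 = time.perf_counter()
    root = np.random.SeedSequence(config.seed)
    psi_rng = np.random.default_rng(root.spawn(1)[0])
    psi = None
    if config.simulation_jitter:
        psi = psi_rng.normal(
            0.0, np.sqrt(config.psi_variance),
            size=(dataset.n_genotypes, dataset.network.n_metabolites),
        )
    model = FluxBalanceModel(dataset, train_mask, scaling, config, psi=psi)
    model.set_prior_locations(scaling.location_target - scaling.alpha)  # mu~/delta

    chain_draws = []
    chain_logp = []
    divergences = 0
    info: dict = {}
    for chain, seq in enumerate(root.spawn(config.chains + 1)[1:]):
        rng = np.random.default_rng(seq)
        theta0 = model.initial_state(rng, init_v=init_fluxes)
        res = nuts_sample(
            model.logp_and_grad, theta0,
            n_iterations=config.iterations, warmup=config.warmup, rng=rng,
            thinning=config.thinning, max_treedepth=config.max_treedepth,
            target_accept=config.target_accept,
        )
        n_kept = len(res.draws)
        if n_kept == 0 or not np.all(np.isfinite(res.draws)):
            raise RuntimeError("sampler returned empty or non-finite draws")
        if res.divergences > 0.5 * (config.iterations - config.warmup):
            raise RuntimeError(
                f"chain {chain}: {res.divergences} divergent transitions out of "
                f"{config.iterations - config.warmup} (more than half); "
                f"step size {res.step_size:.3g}"
            )
        divergences += res.divergences
        chain_draws.append(res.draws)
        chain_logp.append(res.logp)
        info[f"chain{chain}"] = {
            "step_size": res.step_size,
            "mean_accept": res.mean_accept,
            "mean_treedepth": float(np.mean(res.treedepths)),
        }

    draws = np.concatenate(chain_draws, axis=0)
    states = [model.unpack(t) for t in draws]
    samples = PosteriorSamples(
        a=np.array([s.a for s in states]),
        b=np.array([s.b for s in states]),
        sigma2_e=np.array([s.sigma2_e for s in states]),
        sigma2_eps=np.array([s.sigma2_eps for s in states]),
        s_eps=np.array([s.s_eps for s in states]),
        sigma2_v=np.array([s.sigma2_v for s in states]),
        sigma2_u=np.array([s.sigma2_u for s in states]),
        u=np.array([s.u for s in states]),
        v=np.array([s.v for s in states]),
        logp=np.concatenate(chain_logp),
        scaling=scaling,
        config=config,
        target_index=dataset.network.target_reaction_index,
        chains=config.chains,
        divergences=divergences,
        seed=config.seed,
        runtime_s=time.perf_counter() - t0,
        sampler_info=info,
    )
    return samples


def predict_phenotypes(
    samples: PosteriorSamples, genotype_indices: np.ndarray
) -> pd.DataFrame:
    """Posterior mean and central 90% interval of Yhat = a' + b' V''_{i,J}."""
    idx = np.asarray(genotype_indices, dtype=int)
    n = samples.v.shape[1]
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError(f"genotype index outside 0..{n - 1}")
    draws = samples.a[:, None] + samples.b[:, None] * samples.v[:, idx, samples.target_index]
    lo, hi = np.percentile(draws, [5.0, 95.0], axis=0)
    return pd.DataFrame(
        {
            "genotype_index": idx,
            "prediction": draws.mean(axis=0),
            "lower90": lo,
            "upper90": hi,
        }
    )


def _split_chains(x: np.ndarray, chains: int) -> np.ndarray:
    """Reshape (draws, ...) into (2*chains, draws/(2*chains), ...) halves."""
    per = len(x) // chains
    x = x[: per * chains].reshape(chains, per, *x.shape[1:])
    half = per // 2
    return np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)


def convergence_report(samples: PosteriorSamples, threshold: float = RHAT_THRESHOLD) -> pd.DataFrame:
    """Split-R-hat and bulk effective sample size per scalar parameter.

    Each chain is split in half (so a single chain still yields a valid
    split diagnostic); parameters with R-hat above ``threshold`` (default
    1.1) are flagged.  High values are reported, never fatal.
    """
    import arviz as az

    if samples.n_draws // samples.chains < 4:
        raise ValueError("need at least 4 retained draws per chain for split-R-hat")
    named: dict[str, np.ndarray] = {
        "a": samples.a, "b": samples.b,
        "sigma2_e": samples.sigma2_e, "sigma2_eps": samples.sigma2_eps,
        "s_eps": samples.s_eps,
    }
    for j in range(samples.sigma2_v.shape[1]):
        named[f"sigma2_v[{j + 1}]"] = samples.sigma2_v[:, j]
        named[f"sigma2_u[{j + 1}]"] = samples.sigma2_u[:, j]
    tgt = samples.target_index
    for i in range(samples.v.shape[1]):
        named[f"v_target[{i + 1}]"] = samples.v[:, i, tgt]
    rows = []
    for name, x in named.items():
        split = _split_chains(x, samples.chains)
        data = az.convert_to_dataset(split)
        rhat = float(az.rhat(data)["x"].values)
        ess = float(az.ess(data)["x"].values)
        rows.append({"parameter": name, "rhat": rhat, "ess_bulk": ess, "flagged": rhat > threshold})
    return pd.DataFrame(rows)
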