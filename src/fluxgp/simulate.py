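"""Synthetic datasets with the structure of the real biomass panel.

The generator emulates, at configurable size, the statistical features the
method relies on: a sparse signed stoichiometry matrix (median ~4 metabolites
per reaction and ~2 reactions per metabolite, with a few hub metabolites), a
structured SNP panel from which a VanRaden kinship matrix is built,
kinship-correlated genetic flux values per reaction, nonnegativity of
irreversible-reaction fluxes enforced by rejection, exact per-genotype flux
balance obtained by adjusting the coefficient of the last nonzero reaction of
every metabolite, and phenotypes equal to the biomass flux plus Gaussian
noise whose variance is a fixed fraction (default 25%) of the biomass-flux
variance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .core import Dataset, FluxTable, Kinship, PhenotypeVector, ReactionNetwork, vanraden_grm
from .mixedmodel import GeneticParams

__all__ = [
    "SimulationConfig",
    "simulate_snps",
    "simulate_network",
    "sample_reaction_params",
    "simulate_fluxes",
    "simulate_phenotypes",
    "generate_dataset",
    "generate_replicates",
]

_MIN_LAST_FLUX = 1e-6  # |V_last| below this forces a redraw of that genotype


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study conditions."""

    n_genotypes: int = 67
    n_markers: int = 2000
    n_metabolites: int = 10
    n_reactions: int = 12
    metabolites_per_reaction: int = 4   # target median column degree
    reactions_per_metabolite: int = 2   # target median row degree
    irreversible_fraction: float = 0.5
    noise_fraction: float = 0.25
    maf_min: float = 0.05
    maf_max: float = 0.5
    n_clusters: int | None = None       # default: ~6 genotypes per cluster
    cluster_mix: float = 0.2            # per-marker chance to break from the cluster founder
    reaction_params: GeneticParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_markers, self.n_metabolites, self.n_reactions) < 2:
            raise ValueError("N, P, K and J must all be >= 2")
        if not 0.0 < self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must be in (0, 1)")
        if not 0.0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")


def simulate_snps(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """N x P dosage matrix (0/1/2) with cluster-structured relatedness.

    Genotypes belong to clusters sharing a founder haplotype pair; each
    marker is copied from the founder with probability ``1 - cluster_mix``
    and redrawn from the population otherwise.  This yields a kinship matrix
    with strong within-cluster blocks, the regime in which genomic
    prediction of unphenotyped genotypes is informative.
    """
    n, p = config.n_genotypes, config.n_markers
    n_clusters = config.n_clusters or max(2, n // 6)
    freq = rng.uniform(config.maf_min, config.maf_max, size=p)
    founders = rng.binomial(2, freq[None, :], size=(n_clusters, p))
    assign = np.arange(n) % n_clusters
    dosages = founders[assign]
    fresh = rng.binomial(2, freq[None, :], size=(n, p))
    mix = rng.random(size=(n, p)) < config.cluster_mix
    dosages = np.where(mix, fresh, dosages)
    return dosages.astype(np.int64)


def _row_degrees(config: SimulationConfig) -> np.ndarray:
    """Row (metabolite) degrees: median at the target, hubs absorb the rest."""
    K, J = config.n_metabolites, config.n_reactions
    mr, mc = config.reactions_per_metabolite, config.metabolites_per_reaction
    total = mc * J
    base = mr * K
    if total <= base:
        deg = np.full(K, mr)
        deg[: max(0, total - (mr - 1) * K)] = mr  # degenerate; keep >= 2
        return np.maximum(deg, 2)
    extra = total - base
    cap = J - mr
    if cap <= 0:
        raise ValueError("sparsity targets infeasible: row degree target >= n_reactions")
    n_hubs = int(np.ceil(extra / cap))
    if n_hubs > (K - 1) // 2:
        raise ValueError(
            f"sparsity targets infeasible: would need {n_hubs} hub metabolites "
            f"out of {K} to reach {total} entries"
        )
    deg = np.full(K, mr)
    share = extra // n_hubs
    rem = extra - share * n_hubs
    for h in range(n_hubs):
        deg[h] += share + (1 if h < rem else 0)
    return deg


def simulate_network(config: SimulationConfig, rng: np.random.Generator) -> ReactionNetwork:
    """Sparse signed stoichiometry matrix with one target (biomass) reaction.

    Hits the configured median degrees within +-1; every metabolite touches
    at least two reactions (required so the balance adjustment in
    :func:`simulate_fluxes` never empties a row); the last reaction is the
    irreversible biomass drain and consumes every metabolite it touches.
    """
    K, J = config.n_metabolites, config.n_reactions
    mc = config.metabolites_per_reaction
    deg_rows = _row_degrees(config)
    for attempt in range(50):
        # each metabolite joins deg_rows[k] distinct reactions; thin columns
        # are then topped up from the highest-degree (hub) rows, which
        # leaves the row-degree median untouched
        mask = np.zeros((K, J), dtype=bool)
        for k in range(K):
            cols_k = rng.choice(J, size=min(int(deg_rows[k]), J), replace=False)
            mask[k, cols_k] = True
        for jc in range(J):
            while mask[:, jc].sum() < 2:
                candidates = np.nonzero(~mask[:, jc])[0]
                degs_now = mask.sum(axis=1)
                pick = candidates[np.argmax(degs_now[candidates])]
                mask[pick, jc] = True
        m = np.zeros((K, J))
        for j in range(J):
            rows = np.nonzero(mask[:, j])[0]
            mags = rng.choice([1.0, 1.0, 1.0, 2.0, 2.0, 3.0], size=len(rows))
            if j == J - 1:
                signs = -np.ones(len(rows))  # biomass drain consumes precursors
            else:
                signs = np.where(rng.random(len(rows)) < 0.5, 1.0, -1.0)
                if len(rows) >= 2 and len(set(signs)) == 1:
                    signs[rng.integers(len(rows))] *= -1.0
            m[rows, j] = signs * mags
        row_nnz = np.count_nonzero(m, axis=1)
        if row_nnz.min() < 2:
            continue
        med_col = float(np.median(np.count_nonzero(m, axis=0)))
        med_row = float(np.median(row_nnz))
        if abs(med_col - mc) > 1 or abs(med_row - config.reactions_per_metabolite) > 1:
            continue
        irreversible = {J - 1}
        for j in range(J - 1):
            if rng.random() < config.irreversible_fraction:
                irreversible.add(j)
        reversible = set(range(J)) - irreversible
        return ReactionNetwork(
            metabolite_ids=[f"M{k + 1}" for k in range(K)],
            reaction_ids=[f"R{j + 1}" for j in range(J)],
            base_coefficients=m,
            reversible_set=frozenset(reversible),
            irreversible_set=frozenset(irreversible),
            target_reaction_index=J - 1,
        )
    raise ValueError("could not realize a network satisfying the sparsity targets")


def sample_reaction_params(n_reactions: int, rng: np.random.Generator) -> GeneticParams:
    """Per-reaction (mu, sigma2_U, sigma2_V) spanning two orders of magnitude.

    Locations are log-uniform on [1, 100], coefficients of variation
    log-uniform on [0.05, 0.5], heritabilities uniform on [0.5, 0.9].  The
    wide spread of scales is the condition that motivates the per-reaction
    standardization step of the inference model.
    """
    mu = np.exp(rng.uniform(np.log(1.0), np.log(100.0), size=n_reactions))
    cv = np.exp(rng.uniform(np.log(0.05), np.log(0.5), size=n_reactions))
    h2 = rng.uniform(0.5, 0.9, size=n_reactions)
    total = (cv * mu) ** 2
    return GeneticParams(mu=mu, sigma2_u=h2 * total, sigma2_v=(1.0 - h2) * total)


def _draw_v_row(
    u_row: np.ndarray, sd_v: np.ndarray, irr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One genotype's fluxes around its genetic values; irreversible entries
    are redrawn until nonnegative (scalar rejection, bounded)."""
    v = u_row + sd_v * rng.standard_normal(len(u_row))
    bad = irr & (v < 0)
    tries = 0
    while bad.any():
        tries += 1
        if tries > 1000:
            raise RuntimeError("irreversible-flux rejection sampling did not terminate")
        idx = np.nonzero(bad)[0]
        v[idx] = u_row[idx] + sd_v[idx] * rng.standard_normal(len(idx))
        bad = irr & (v < 0)
    return v


def simulate_fluxes(
    network: ReactionNetwork,
    kinship: Kinship,
    params: GeneticParams,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[FluxTable, ReactionNetwork, np.ndarray]:
    """Kinship-correlated fluxes plus the balancing coefficient overrides.

    For each reaction j the genetic values U_{,j} ~ N(1 mu_j, G sigma2_Uj)
    (redrawn whole if an irreversible reaction gets a negative entry) and
    observed fluxes V_{i,j} ~ N(U_{i,j}, sigma2_Vj) truncated at zero for
    irreversible reactions.  Exact steady state is then imposed per genotype
    by overriding, for every metabolite, the coefficient of its last nonzero
    reaction:  M_i,last,k = -(sum over the other reactions of M_k,j V_i,j)
    / V_i,last.  Genotypes with |V_i,last| < 1e-6 for any metabolite are
    redrawn (bounded retries).

    Returns the flux table, a copy of the network carrying the per-genotype
    overrides, and the matrix of genetic values U.
    """
    n = kinship.n_genotypes
    J = network.n_reactions
    if len(params.mu) != J:
        raise ValueError("reaction parameters must cover every reaction")
    w, q = np.linalg.eigh(kinship.values)
    chol_g = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    irr = network.irreversible_mask
    sd_u = np.sqrt(params.sigma2_u)
    sd_v = np.sqrt(params.sigma2_v)

    u = np.empty((n, J))
    for j in range(J):
        for attempt in range(1000):
            uj = params.mu[j] + sd_u[j] * (chol_g @ rng.standard_normal(n))
            if not irr[j] or uj.min() >= 0.0:
                break
        else:
            raise RuntimeError(
                f"genetic values for irreversible reaction {j + 1} never all-nonnegative; "
                f"mu={params.mu[j]:.3g}, sd={sd_u[j]:.3g}"
            )
        u[:, j] = uj

    base = network.base_coefficients
    last = np.array([np.nonzero(base[k])[0][-1] for k in range(network.n_metabolites)])
    v = np.empty((n, J))
    for i in range(n):
        for attempt in range(max_retries):
            vi = _draw_v_row(u[i], sd_v, irr, rng)
            if np.all(np.abs(vi[last]) >= _MIN_LAST_FLUX):
                break
        else:
            raise RuntimeError(
                f"genotype {i + 1}: |V| at a balancing reaction stayed below "
                f"{_MIN_LAST_FLUX} after {max_retries} redraws"
            )
        v[i] = vi

    overrides: dict[tuple[int, int, int], float] = {}
    for k in range(network.n_metabolites):
        cols = np.nonzero(base[k])[0]
        others = cols[cols != last[k]]
        for i in range(n):
            resid = float(base[k, others] @ v[i, others])
            overrides[(i, k, int(last[k]))] = -resid / float(v[i, last[k]])

    adjusted = ReactionNetwork(
        metabolite_ids=list(network.metabolite_ids),
        reaction_ids=list(network.reaction_ids),
        base_coefficients=base.copy(),
        reversible_set=network.reversible_set,
        irreversible_set=network.irreversible_set,
        target_reaction_index=network.target_reaction_index,
        genotype_overrides=overrides,
    )
    ids = [f"g{i + 1}" for i in range(n)] if kinship.genotype_ids is None else list(kinship.genotype_ids)
    return FluxTable(values=v, genotype_ids=ids), adjusted, u


def simulate_phenotypes(
    fluxes: FluxTable,
    target_index: int,
    noise_fraction: float,
    rng: np.random.Generator,
) -> PhenotypeVector:
    """Y = biomass flux + N(0, noise_fraction * var(biomass flux))."""
    if not 0.0 < noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in (0, 1)")
    target = fluxes.values[:, target_index]
    var = float(np.var(target, ddof=1))
    if var <= 0.0:
        raise ValueError("target flux has zero variance; nothing to scale noise against")
    noise = rng.normal(0.0, np.sqrt(noise_fraction * var), size=len(target))
    return PhenotypeVector(values=target + noise, mask=np.ones(len(target), dtype=bool))


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Full pipeline: SNPs -> kinship -> network -> fluxes -> phenotypes."""
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(5)
    rng_snp, rng_net, rng_par, rng_flux, rng_phen = (np.random.default_rng(s) for s in seeds)

    dosages = simulate_snps(config, rng_snp)
    ids = [f"g{i + 1}" for i in range(config.n_genotypes)]
    kinship = vanraden_grm(dosages, genotype_ids=ids)
    network = simulate_network(config, rng_net)
    params = config.reaction_params or sample_reaction_params(config.n_reactions, rng_par)
    fluxes, adjusted, u = simulate_fluxes(network, kinship, params, rng_flux)
    fluxes.genotype_ids = ids
    phenotypes = simulate_phenotypes(
        fluxes, network.target_reaction_index, config.noise_fraction, rng_phen
    )
    cfg = asdict(config)
    cfg["reaction_params"] = None
    meta = {
        "seed": config.seed,
        "sub_seeds": [int(s.generate_state(1)[0]) for s in seeds],
        "config": cfg,
        "reaction_mu": params.mu.tolist(),
        "reaction_sigma2_u": params.sigma2_u.tolist(),
        "reaction_sigma2_v": params.sigma2_v.tolist(),
    }
    return Dataset(
        network=adjusted,
        kinship=kinship,
        phenotypes=phenotypes,
        true_fluxes=fluxes,
        reference_genotype_index=0,
        metadata=meta,
    )


def generate_replicates(config: SimulationConfig, n_replicates: int = 10) -> list[Dataset]:
    """Independent replicate datasets with recorded distinct sub-seeds."""
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    kwargs = asdict(config)
    kwargs["reaction_params"] = config.reaction_params
    out = []
    for rep, child in enumerate(children):
        kwargs["seed"] = int(child.generate_state(1)[0] % (2**31 - 1))
        ds = generate_dataset(SimulationConfig(**kwargs))
        ds.metadata["replicate"] = rep
        out.append(ds)
    return out
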