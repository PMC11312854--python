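"""Domain types and flux-balance arithmetic.

The central objects are a stoichiometric reaction network (metabolites x
reactions matrix of signed coefficients, with a designated biomass-producing
target reaction and a reversible/irreversible partition of the reactions), a
table of per-genotype reaction fluxes, a genomic relationship (kinship)
matrix, and a phenotype vector.  Steady state for genotype ``i`` means
``M_i @ v_i = 0``: every metabolite's production balances its consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReactionNetwork",
    "FluxTable",
    "Kinship",
    "PhenotypeVector",
    "Dataset",
    "validate_network",
    "balance_residuals",
    "vanraden_grm",
]

#: tolerance below which a kinship eigenvalue is repaired by jitter
_PSD_TOL = 1e-8


@dataclass
class ReactionNetwork:
    """Stoichiometric network shared by all genotypes.

    ``base_coefficients`` is the K x J matrix of the reference genotype;
    positive coefficients produce the metabolite, negative ones consume it.
    ``genotype_overrides`` maps ``(genotype, metabolite, reaction)`` index
    triples to replacement coefficients, so genotype-specific stoichiometry
    (e.g. the biomass column) is stored sparsely on top of the shared base.
    Indices are 0-based in memory; file formats and messages are 1-based.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    base_coefficients: np.ndarray
    reversible_set: frozenset[int]
    irreversible_set: frozenset[int]
    target_reaction_index: int
    genotype_overrides: dict[tuple[int, int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base_coefficients = np.asarray(self.base_coefficients, dtype=float)
        self.reversible_set = frozenset(self.reversible_set)
        self.irreversible_set = frozenset(self.irreversible_set)

    @property
    def n_metabolites(self) -> int:
        return self.base_coefficients.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.base_coefficients.shape[1]

    def coefficients_for(self, genotype: int) -> np.ndarray:
        """Effective K x J matrix for one genotype (base + overrides)."""
        m = self.base_coefficients.copy()
        for (g, k, j), c in self.genotype_overrides.items():
            if g == genotype:
                m[k, j] = c
        return m

    def stacked_coefficients(self, n_genotypes: int) -> np.ndarray:
        """N x K x J array of effective matrices for genotypes 0..N-1."""
        out = np.broadcast_to(
            self.base_coefficients, (n_genotypes,) + self.base_coefficients.shape
        ).copy()
        for (g, k, j), c in self.genotype_overrides.items():
            if g < n_genotypes:
                out[g, k, j] = c
        return out

    @property
    def irreversible_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_reactions, dtype=bool)
        mask[sorted(self.irreversible_set)] = True
        return mask


@dataclass
class FluxTable:
    """N x J matrix of reaction fluxes with genotype labels."""

    values: np.ndarray
    genotype_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.values.shape[1]


@dataclass
class Kinship:
    """N x N genomic relationship matrix (VanRaden form or compatible)."""

    values: np.ndarray
    genotype_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"kinship matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric within 1e-10")
        w = np.linalg.eigvalsh(v)
        if w[0] < -_PSD_TOL:
            raise ValueError(
                f"kinship matrix is indefinite (min eigenvalue {w[0]:.3e} < -1e-8)"
            )
        if w[0] < 0.0:
            # small numerical indefiniteness: repair once with fixed jitter
            self.values = v + _PSD_TOL * np.eye(v.shape[0])

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]


@dataclass
class PhenotypeVector:
    """Trait values with an observed mask (False = held out / missing)."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("phenotype values and mask differ in length")


@dataclass
class Dataset:
    """Network, kinship and phenotypes for one panel of genotypes."""

    network: ReactionNetwork
    kinship: Kinship
    phenotypes: PhenotypeVector
    true_fluxes: FluxTable | None = None
    reference_genotype_index: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.kinship.n_genotypes
        if len(self.phenotypes.values) != n:
            raise ValueError(
                f"phenotype length {len(self.phenotypes.values)} != kinship size {n}"
            )
        if self.true_fluxes is not None:
            if self.true_fluxes.n_genotypes != n:
                raise ValueError("flux table and kinship disagree on genotype count")
            if self.true_fluxes.genotype_ids != self.kinship.genotype_ids:
                raise ValueError("flux table and kinship disagree on genotype ids")

    @property
    def n_genotypes(self) -> int:
        return self.kinship.n_genotypes

    @property
    def genotype_ids(self) -> list[str]:
        return self.kinship.genotype_ids


def validate_network(network: ReactionNetwork) -> list[str]:
    """Check the network invariants; return a list of violations (empty = ok).

    Reported indices are 1-based to match the file formats.
    """
    report: list[str] = []
    K, J = network.base_coefficients.shape
    rev, irr = network.reversible_set, network.irreversible_set
    overlap = rev & irr
    for j in sorted(overlap):
        report.append(f"reaction {j + 1} is flagged both reversible and irreversible")
    missing = set(range(J)) - (rev | irr)
    for j in sorted(missing):
        report.append(f"reaction {j + 1} is in neither the reversible nor irreversible set")
    out_of_range = [j for j in rev | irr if j < 0 or j >= J]
    for j in sorted(out_of_range):
        report.append(f"reversibility set refers to nonexistent reaction index {j + 1}")
    if not (0 <= network.target_reaction_index < J):
        report.append(
            f"target reaction index {network.target_reaction_index + 1} outside 1..{J}"
        )
    nnz = np.count_nonzero(network.base_coefficients, axis=1)
    for k in np.nonzero(nnz == 0)[0]:
        name = network.metabolite_ids[k] if k < len(network.metabolite_ids) else str(k + 1)
        report.append(f"metabolite {name} (row {k + 1}) has no nonzero coefficient")
    if len(network.metabolite_ids) != K:
        report.append(
            f"{len(network.metabolite_ids)} metabolite ids for {K} matrix rows"
        )
    if len(network.reaction_ids) != J:
        report.append(f"{len(network.reaction_ids)} reaction ids for {J} matrix columns")
    return report


def balance_residuals(network: ReactionNetwork, fluxes: FluxTable) -> np.ndarray:
    """Per-genotype steady-state residuals ``M_i @ v_i``, shape N x K.

    The result is the zero matrix iff every genotype is at exact flux
    balance under its own (override-adjusted) stoichiometry.
    """
    if fluxes.n_reactions != network.n_reactions:
        raise ValueError(
            f"reaction axis mismatch: flux table has {fluxes.n_reactions} columns, "
            f"network has {network.n_reactions} reactions"
        )
    n = fluxes.n_genotypes
    stacked = network.stacked_coefficients(n)
    return np.einsum("ikj,ij->ik", stacked, fluxes.values)


def vanraden_grm(snp_dosages: np.ndarray, genotype_ids: list[str] | None = None) -> Kinship:
    """Genomic relationship matrix from 0/1/2 SNP dosages.

    G = Z Z' / (2 * sum_p p(1-p)) with Z the column-centered dosages and p
    the observed allele frequencies.
    """
    x = np.asarray(snp_dosages, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("dosage matrix must be N x P with P >= 1")
    p = x.mean(axis=0) / 2.0
    het = p * (1.0 - p)
    denom = 2.0 * het.sum()
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic; VanRaden denominator is zero")
    z = x - 2.0 * p
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)
    if genotype_ids is None:
        genotype_ids = [f"g{i + 1}" for i in range(x.shape[0])]
    return Kinship(values=g, genotype_ids=list(genotype_ids))
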