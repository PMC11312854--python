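"""Tab-separated on-disk layout for datasets.

A dataset directory contains:

* ``network.tsv``    — ``metabolite`` column + one numeric column per reaction
* ``reactions.tsv``  — ``reaction_id``, ``reversible`` (0/1), ``is_target`` (0/1)
* ``overrides.tsv``  — ``genotype_id``, ``metabolite_id``, ``reaction_id``,
  ``coefficient`` (optional; genotype-specific stoichiometry)
* ``kinship.tsv``    — square matrix, genotype ids as header and first column
* ``phenotypes.tsv`` — ``genotype_id``, ``value`` (``NA`` = unobserved)
* ``fluxes.tsv``     — optional true fluxes (simulated data only)
* ``metadata.json``  — seeds, config, reference genotype

All round trips are lossless: numbers are written with ``repr`` precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, FluxTable, Kinship, PhenotypeVector, ReactionNetwork

__all__ = ["save_dataset", "load_dataset"]

_FLOAT_FMT = "%.17g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def save_dataset(dataset: Dataset, directory: str | Path) -> Path:
    """Write a dataset to ``directory`` (created if absent); returns the path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    net = dataset.network
    ids = dataset.genotype_ids

    mat = pd.DataFrame(net.base_coefficients, columns=net.reaction_ids)
    mat.insert(0, "metabolite", net.metabolite_ids)
    _write_tsv(mat, d / "network.tsv")

    irr = net.irreversible_mask
    rx = pd.DataFrame(
        {
            "reaction_id": net.reaction_ids,
            "reversible": (~irr).astype(int),
            "is_target": [
                int(j == net.target_reaction_index) for j in range(net.n_reactions)
            ],
        }
    )
    _write_tsv(rx, d / "reactions.tsv")

    if net.genotype_overrides:
        rows = [
            {
                "genotype_id": ids[g],
                "metabolite_id": net.metabolite_ids[k],
                "reaction_id": net.reaction_ids[j],
                "coefficient": c,
            }
            for (g, k, j), c in sorted(net.genotype_overrides.items())
        ]
        _write_tsv(pd.DataFrame(rows), d / "overrides.tsv")

    kin = pd.DataFrame(dataset.kinship.values, columns=ids)
    kin.insert(0, "genotype_id", ids)
    _write_tsv(kin, d / "kinship.tsv")

    ph = pd.DataFrame(
        {
            "genotype_id": ids,
            "value": [
                (_FLOAT_FMT % v) if m else "NA"
                for v, m in zip(dataset.phenotypes.values, dataset.phenotypes.mask)
            ],
        }
    )
    ph.to_csv(d / "phenotypes.tsv", sep="\t", index=False)

    if dataset.true_fluxes is not None:
        fl = pd.DataFrame(dataset.true_fluxes.values, columns=net.reaction_ids)
        fl.insert(0, "genotype_id", ids)
        _write_tsv(fl, d / "fluxes.tsv")

    meta = dict(dataset.metadata)
    if dataset.reference_genotype_index is not None:
        meta["reference_genotype_id"] = ids[dataset.reference_genotype_index]
    (d / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return d


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def load_dataset(directory: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    d = Path(directory)

    mat = pd.read_csv(d / "network.tsv", sep="\t", float_precision="round_trip")
    _require_columns(mat, ["metabolite"], d / "network.tsv")
    metabolite_ids = mat["metabolite"].astype(str).tolist()
    reaction_ids = [c for c in mat.columns if c != "metabolite"]
    coeffs = mat[reaction_ids].to_numpy(dtype=float)

    rx = pd.read_csv(d / "reactions.tsv", sep="\t")
    _require_columns(rx, ["reaction_id", "reversible", "is_target"], d / "reactions.tsv")
    rx_ids = rx["reaction_id"].astype(str).tolist()
    if rx_ids != [str(r) for r in reaction_ids]:
        raise ValueError(
            f"{d / 'reactions.tsv'}: reaction ids disagree with network.tsv columns"
        )
    rev_flags = rx["reversible"].to_numpy(dtype=int)
    reversible = frozenset(int(j) for j in np.nonzero(rev_flags == 1)[0])
    irreversible = frozenset(int(j) for j in np.nonzero(rev_flags == 0)[0])
    targets = np.nonzero(rx["is_target"].to_numpy(dtype=int) == 1)[0]
    if len(targets) != 1:
        raise ValueError(
            f"{d / 'reactions.tsv'}: expected exactly one is_target=1 row, found {len(targets)}"
        )

    kin = pd.read_csv(d / "kinship.tsv", sep="\t", float_precision="round_trip")
    _require_columns(kin, ["genotype_id"], d / "kinship.tsv")
    ids = kin["genotype_id"].astype(str).tolist()
    if [c for c in kin.columns if c != "genotype_id"] != ids:
        raise ValueError(f"{d / 'kinship.tsv'}: header ids disagree with first column")
    kinship = Kinship(values=kin[ids].to_numpy(dtype=float), genotype_ids=ids)

    ph = pd.read_csv(d / "phenotypes.tsv", sep="\t", keep_default_na=False,
                     dtype={"genotype_id": str, "value": str})
    _require_columns(ph, ["genotype_id", "value"], d / "phenotypes.tsv")
    ph_ids = ph["genotype_id"].tolist()
    unknown = sorted(set(ph_ids) - set(ids))
    if unknown:
        raise ValueError(
            f"{d / 'phenotypes.tsv'}: genotype(s) {unknown} absent from kinship.tsv"
        )
    if ph_ids != ids:
        raise ValueError(f"{d / 'phenotypes.tsv'}: genotype order disagrees with kinship.tsv")
    raw = ph["value"].tolist()
    mask = np.array([v != "NA" for v in raw], dtype=bool)
    values = np.array([float(v) if v != "NA" else np.nan for v in raw], dtype=float)
    phenotypes = PhenotypeVector(values=values, mask=mask)

    overrides: dict[tuple[int, int, int], float] = {}
    ov_path = d / "overrides.tsv"
    if ov_path.exists():
        ov = pd.read_csv(ov_path, sep="\t", float_precision="round_trip", dtype={"genotype_id": str, "metabolite_id": str, "reaction_id": str})
        _require_columns(
            ov, ["genotype_id", "metabolite_id", "reaction_id", "coefficient"], ov_path
        )
        gid_ix = {g: i for i, g in enumerate(ids)}
        met_ix = {m: i for i, m in enumerate(metabolite_ids)}
        rxn_ix = {str(r): i for i, r in enumerate(reaction_ids)}
        for row in ov.itertuples(index=False):
            try:
                key = (gid_ix[row.genotype_id], met_ix[row.metabolite_id], rxn_ix[row.reaction_id])
            except KeyError as exc:
                raise ValueError(f"{ov_path}: unknown id {exc}") from exc
            overrides[key] = float(row.coefficient)

    network = ReactionNetwork(
        metabolite_ids=metabolite_ids,
        reaction_ids=[str(r) for r in reaction_ids],
        base_coefficients=coeffs,
        reversible_set=reversible,
        irreversible_set=irreversible,
        target_reaction_index=int(targets[0]),
        genotype_overrides=overrides,
    )

    true_fluxes = None
    fl_path = d / "fluxes.tsv"
    if fl_path.exists():
        fl = pd.read_csv(fl_path, sep="\t", float_precision="round_trip")
        _require_columns(fl, ["genotype_id"], fl_path)
        if fl["genotype_id"].astype(str).tolist() != ids:
            raise ValueError(f"{fl_path}: genotype order disagrees with kinship.tsv")
        true_fluxes = FluxTable(
            values=fl[[str(r) for r in reaction_ids]].to_numpy(dtype=float),
            genotype_ids=ids,
        )

    metadata: dict = {}
    meta_path = d / "metadata.json"
    reference_index = None
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
        ref_id = metadata.get("reference_genotype_id")
        if ref_id is not None:
            if ref_id not in ids:
                raise ValueError(f"{meta_path}: reference genotype {ref_id!r} unknown")
            reference_index = ids.index(ref_id)

    return Dataset(
        network=network,
        kinship=kinship,
        phenotypes=phenotypes,
        true_fluxes=true_fluxes,
        reference_genotype_index=reference_index,
        metadata=metadata,
    )
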