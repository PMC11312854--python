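"""Cross-validation harness, accuracy metrics and method comparison.

Accuracy is the Pearson correlation R between observed and predicted
phenotypes, computed within each CV fold.  Methods (GBLUP, the
predict-then-project QP baseline, and the proposed joint model over a grid
of likelihood weights W) are compared by two-sided Mann-Whitney-Wilcoxon
tests on the pooled fold-level R values with Bonferroni correction, and
summarized figure-style with shared significance letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr

from .bayes import fit_model, predict_phenotypes
from .core import Dataset
from .mixedmodel import estimate_reaction_params, gblup_predict, reml_single_kernel
from .model import ModelConfig
from .qp import QPSettings, estimate_training_fluxes, qp_predict_pipeline
from .core import FluxTable
from .scaling import compute_scaling, transform_fluxes

__all__ = [
    "W_GRID",
    "FoldAssignment",
    "make_cv_folds",
    "pearson_by_fold",
    "compare_methods",
    "run_benchmark",
]

W_GRID = (0.16, 0.32, 0.48, 0.64, 0.80, 0.96)


@dataclass
class FoldAssignment:
    """One repeat of a k-fold partition of the genotypes."""

    repeat: int
    folds: list[np.ndarray]
    seed: int = 0

    def __post_init__(self) -> None:
        self.folds = [np.asarray(f, dtype=int) for f in self.folds]
        all_idx = np.concatenate(self.folds)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("folds overlap")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes {sizes} differ by more than 1")

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[fold]
        train = np.concatenate([f for q, f in enumerate(self.folds) if q != fold])
        return np.sort(train), np.sort(test)


def make_cv_folds(
    n_genotypes: int, k: int = 3, n_repeats: int = 1, seed: int = 0
) -> list[FoldAssignment]:
    """Uniformly random k-fold partitions, one FoldAssignment per repeat."""
    if k > n_genotypes:
        raise ValueError(f"cannot make {k} folds from {n_genotypes} genotypes")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_repeats):
        perm = rng.permutation(n_genotypes)
        out.append(
            FoldAssignment(repeat=rep, folds=list(np.array_split(perm, k)), seed=seed)
        )
    return out


def pearson_by_fold(
    y_true: np.ndarray, y_pred: np.ndarray, folds: FoldAssignment
) -> list[float]:
    """Pearson R within each fold; NaN (with a warning) on zero variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    out = []
    for q, fold in enumerate(folds.folds):
        yt, yp = y_true[fold], y_pred[fold]
        ok = np.isfinite(yt) & np.isfinite(yp)
        if ok.sum() < 3:
            warnings.warn(f"fold {q + 1}: fewer than 3 usable predictions")
            out.append(float("nan"))
            continue
        if np.var(yt[ok]) == 0 or np.var(yp[ok]) == 0:
            warnings.warn(f"fold {q + 1}: zero variance; correlation undefined")
            out.append(float("nan"))
            continue
        out.append(float(pearsonr(yt[ok], yp[ok])[0]))
    return out


def _assign_letters(labels: list[str], medians: dict[str, float], sig: set[frozenset]) -> dict[str, str]:
    """Compact letter display: labels share a letter iff not significantly
    different from every current member of that letter's group."""
    order = sorted(labels, key=lambda m: -medians[m])
    groups: list[list[str]] = []
    for lab in order:
        placed = False
        for grp in groups:
            if all(frozenset((lab, other)) not in sig for other in grp):
                grp.append(lab)
                placed = True
        if not placed:
            groups.append([lab])
    letters = {lab: "" for lab in labels}
    for gi, grp in enumerate(groups):
        ch = chr(ord("a") + gi)
        for lab in grp:
            letters[lab] += ch
    return letters


def compare_methods(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Mann-Whitney-Wilcoxon tests on pooled fold-level R values.

    ``results`` needs columns ``label`` and ``r``.  Exact p-values for
    group sizes up to 20, normal approximation (tie-corrected) beyond.
    Bonferroni correction over all pairs; the returned table carries raw
    and adjusted p-values plus shared significance letters.
    """
    if "label" not in results or "r" not in results:
        raise ValueError("results must have 'label' and 'r' columns")
    groups = {lab: g["r"].dropna().to_numpy() for lab, g in results.groupby("label")}
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need at least two methods to compare")
    for lab, vals in groups.items():
        if len(vals) < 5:
            raise ValueError(f"method {lab!r} has fewer than 5 fold-level R values")
    pairs = [(a, b) for qi, a in enumerate(labels) for b in labels[qi + 1:]]
    n_pairs = len(pairs)
    rows = []
    sig: set[frozenset] = set()
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        method = "exact" if max(len(xa), len(xb)) <= 20 else "asymptotic"
        stat, p = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        p_adj = min(1.0, p * n_pairs)
        if p_adj < alpha:
            sig.add(frozenset((a, b)))
        rows.append({"method_a": a, "method_b": b, "u_statistic": float(stat),
                     "p_value": float(p), "p_bonferroni": p_adj,
                     "significant": p_adj < alpha})
    table = pd.DataFrame(rows)
    medians = {lab: float(np.median(v)) for lab, v in groups.items()}
    letters = _assign_letters(labels, medians, sig)
    table.attrs["letters"] = letters
    table.attrs["medians"] = medians
    return table


def _gblup_fold(dataset: Dataset, train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
    y = dataset.phenotypes.values
    k_tt = dataset.kinship.values[np.ix_(train_idx, train_idx)]
    fit = reml_single_kernel(y[train_idx], k_tt)
    return gblup_predict(fit, dataset.kinship, train_idx, test_idx)


def _proposed_fold(
    dataset: Dataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    weight: float,
    config: ModelConfig,
    qp_settings: QPSettings,
    fold_seed: int,
    vt_cache: dict,
) -> np.ndarray:
    """One fold of the proposed model: training fluxes -> rough estimates ->
    scaling -> NUTS fit (constraints over all genotypes, phenotypes of the
    training genotypes only) -> posterior-mean prediction for the fold."""
    key = tuple(train_idx)
    if key not in vt_cache:
        settings = QPSettings(**{**qp_settings.__dict__,
                                 "reference_genotype_index": dataset.reference_genotype_index})
        ref_fluxes = dataset.true_fluxes.values[dataset.reference_genotype_index]
        vt = estimate_training_fluxes(
            dataset.network, dataset.phenotypes, ref_fluxes, settings, train_idx
        )
        k_tt = dataset.kinship.values[np.ix_(train_idx, train_idx)]
        rough = estimate_reaction_params(vt, k_tt)
        vt_cache[key] = (vt, rough)
    vt, rough = vt_cache[key]
    scaling = compute_scaling(rough, config.location_target, mode=config.delta_mode)
    n = dataset.n_genotypes
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True
    # chains start on each genotype's steady-state manifold: training rows at
    # their QP-estimated fluxes, held-out rows at the balanced projection of
    # the rough per-reaction locations (uses only the stoichiometry)
    from .qp import project_to_balance

    irr = dataset.network.irreversible_mask
    init_nat = np.empty((n, dataset.network.n_reactions))
    init_nat[train_idx] = vt.values
    for i in test_idx:
        try:
            init_nat[i] = project_to_balance(
                rough.mu, dataset.network.coefficients_for(i), irr, qp_settings
            )
        except RuntimeError:
            init_nat[i] = rough.mu
    init_v = transform_fluxes(
        FluxTable(values=init_nat, genotype_ids=list(dataset.genotype_ids)), scaling
    ).values
    cfg = ModelConfig(**{**config.__dict__, "weight": weight, "seed": fold_seed})
    samples = fit_model(dataset, train_mask, scaling, cfg, init_fluxes=init_v)
    return predict_phenotypes(samples, test_idx)["prediction"].to_numpy(), samples


def run_benchmark(
    datasets: list[Dataset],
    methods: tuple[str, ...] = ("gblup", "qp", "proposed"),
    w_grid: tuple[float, ...] = W_GRID,
    k_folds: int = 3,
    config: ModelConfig | None = None,
    qp_settings: QPSettings | None = None,
    seed: int = 0,
    folds_per_dataset: list[FoldAssignment] | None = None,
) -> pd.DataFrame:
    """Fold-wise accuracy for each method (and weight) on each dataset.

    Returns a long DataFrame with columns ``method``, ``weight``,
    ``label``, ``repeat`` (dataset/replicate index), ``fold``, ``r``.
    Individual fold failures are recorded as NaN and the run continues.
    Fully deterministic given ``seed``.
    """
    bad = set(methods) - {"gblup", "qp", "proposed"}
    if bad:
        raise ValueError(f"unknown method(s): {sorted(bad)}")
    config = config or ModelConfig()
    qp_settings = qp_settings or QPSettings()
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, dataset in enumerate(datasets):
        if folds_per_dataset is not None:
            folds = folds_per_dataset[rep]
        else:
            fold_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            folds = make_cv_folds(dataset.n_genotypes, k=k_folds, seed=fold_seed)[0]
            folds.repeat = rep
        y = dataset.phenotypes.values
        vt_cache: dict = {}
        preds: dict[str, np.ndarray] = {}
        for method in methods:
            if method == "proposed":
                labels = [(f"PM-{w:g}", w) for w in w_grid]
            else:
                labels = [(method, None)]
            for label, w in labels:
                preds[label] = np.full(dataset.n_genotypes, np.nan)
        for fold in range(k_folds):
            train_idx, test_idx = folds.split(fold)
            if "gblup" in methods:
                try:
                    preds["gblup"][test_idx] = _gblup_fold(dataset, train_idx, test_idx)
                except (ValueError, RuntimeError) as exc:
                    warnings.warn(f"gblup failed on replicate {rep} fold {fold}: {exc}")
            if "qp" in methods:
                try:
                    out = qp_predict_pipeline(dataset, train_idx, test_idx, qp_settings)
                    preds["qp"][test_idx] = out["predictions"]
                except (ValueError, RuntimeError) as exc:
                    warnings.warn(f"qp failed on replicate {rep} fold {fold}: {exc}")
            if "proposed" in methods:
                # one chain seed per fold, shared across the weight grid
                # (common random numbers: the accuracy-vs-W profile then
                # reflects the weight's effect, not chain-to-chain noise)
                fseed = int(
                    np.random.SeedSequence([seed, rep, fold])
                    .generate_state(1)[0] % (2**31 - 1)
                )
                for w in w_grid:
                    try:
                        p, _ = _proposed_fold(
                            dataset, train_idx, test_idx, w, config, qp_settings,
                            fseed, vt_cache,
                        )
                        preds[f"PM-{w:g}"][test_idx] = p
                    except (ValueError, RuntimeError) as exc:
                        warnings.warn(
                            f"proposed (W={w}) failed on replicate {rep} fold {fold}: {exc}"
                        )
        for label, p in preds.items():
            rs = pearson_by_fold(y, p, folds)
            w = float(label.split("-")[1]) if label.startswith("PM-") else np.nan
            method = "proposed" if label.startswith("PM-") else label
            for fold, r in enumerate(rs):
                rows.append({"method": method, "weight": w, "label": label,
                             "repeat": rep, "fold": fold, "r": r})
    return pd.DataFrame(rows)
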