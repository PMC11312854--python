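"""Predict-then-project baseline.

Three stages, each per genotype or per reaction:

1. training-flux estimation — for every training genotype a quadratic
   program finds the balanced flux vector closest (in relative deviation)
   to the reference genotype's fluxes while matching the biomass ratio
   ``V_{i,J} = V_{ref,J} * Y_i / Y_ref``;
2. per-reaction GBLUP predicts test-genotype fluxes from kinship;
3. the predicted (unbalanced) fluxes of each test genotype are projected
   back onto the steady-state polytope by a second quadratic program, and
   the projected biomass flux is the phenotype prediction.

Equality (balance) constraints are eliminated through a nullspace basis,
so they hold to machine precision; inequality constraints (irreversible
fluxes, optional physiological box constraints between reaction pairs) are
handled by an active solve only when the unconstrained minimizer violates
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import LinearConstraint, minimize

from .core import Dataset, FluxTable, Kinship, PhenotypeVector, ReactionNetwork
from .mixedmodel import gblup_predict, reml_single_kernel

__all__ = ["QPSettings", "estimate_training_fluxes", "predict_flux_genetics",
           "project_to_balance", "qp_predict_pipeline"]

_SMALL_DENOM = 1e-6


@dataclass
class QPSettings:
    """Projection options.

    The optional physiological ("additional") constraints bound the
    carboxylation flux by the oxygenation flux and the starch flux by the
    sucrose flux; the four reaction indices must be supplied when the flag
    is on.  They default to off, the protocol the method settles on.
    """

    use_additional_constraints: bool = False
    oxygenation_index: int | None = None
    carboxylation_index: int | None = None
    sucrose_index: int | None = None
    starch_index: int | None = None
    oxg_car_bounds: tuple[float, float] = (0.94, 3.81)
    suc_sta_bounds: tuple[float, float] = (0.79, 3.37)
    tolerance: float = 1e-8
    reference_genotype_index: int | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.oxg_car_bounds, self.suc_sta_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive with lower < upper")
        if self.use_additional_constraints:
            idx = [self.oxygenation_index, self.carboxylation_index,
                   self.sucrose_index, self.starch_index]
            if any(i is None for i in idx) or len(set(idx)) != 4:
                raise ValueError(
                    "additional constraints need four distinct reaction indices"
                )


def _objective_weights(anchor: np.ndarray) -> np.ndarray:
    """Diagonal weights q_j for sum q_j (V_j - anchor_j)^2.

    q_j = 1/anchor_j^2 (relative deviation) except where |anchor_j| is
    negligible, where the term switches to absolute deviation scaled by the
    median |anchor| so the program stays well-posed.
    """
    a = np.abs(np.asarray(anchor, dtype=float))
    good = a >= _SMALL_DENOM
    med = np.median(a[good]) if good.any() else 1.0
    med = med if med > 0 else 1.0
    q = np.empty_like(a)
    q[good] = 1.0 / a[good] ** 2
    q[~good] = 1.0 / med ** 2
    return q


def _ineq_rows(n_reactions: int, irr_idx: np.ndarray, settings: QPSettings):
    """Rows G, lower bounds h of the inequality system G V >= h."""
    rows = []
    for jdx in irr_idx:
        e = np.zeros(n_reactions)
        e[jdx] = 1.0
        rows.append(e)
    if settings.use_additional_constraints:
        lo1, hi1 = settings.oxg_car_bounds
        lo2, hi2 = settings.suc_sta_bounds
        oxg, car = settings.oxygenation_index, settings.carboxylation_index
        suc, sta = settings.sucrose_index, settings.starch_index
        for a_ix, b_ix, coef, sign in (
            (car, oxg, lo1, 1.0), (car, oxg, hi1, -1.0),
            (sta, suc, lo2, 1.0), (sta, suc, hi2, -1.0),
        ):
            e = np.zeros(n_reactions)
            e[a_ix] = sign
            e[b_ix] = -sign * coef
            rows.append(e)
    if not rows:
        return np.zeros((0, n_reactions)), np.zeros(0)
    return np.asarray(rows), np.zeros(len(rows))


def _solve_anchored_qp(
    anchor: np.ndarray,
    eq_a: np.ndarray,
    eq_b: np.ndarray,
    irr_idx: np.ndarray,
    settings: QPSettings,
) -> np.ndarray:
    """min sum q_j (V_j - anchor_j)^2  s.t.  eq_a V = eq_b, G V >= 0."""
    j = len(anchor)
    q = _objective_weights(anchor)
    if eq_a.size:
        v0, *_ = np.linalg.lstsq(eq_a, eq_b, rcond=None)
        if np.max(np.abs(eq_a @ v0 - eq_b)) > 1e-6 * max(1.0, np.abs(eq_b).max(initial=1.0)):
            raise RuntimeError("equality constraints are inconsistent (no balanced solution)")
        z = null_space(eq_a)
    else:
        v0 = np.zeros(j)
        z = np.eye(j)
    g_rows, h = _ineq_rows(j, irr_idx, settings)

    if z.shape[1] == 0:
        v = v0
        if g_rows.size and np.any(g_rows @ v < h - settings.tolerance):
            raise RuntimeError("equality constraints admit a unique infeasible point")
        return v

    hess = 2.0 * (z.T * q) @ z
    lin = 2.0 * z.T @ (q * (v0 - anchor))
    t_free = np.linalg.solve(hess, -lin)
    v = v0 + z @ t_free
    if not g_rows.size or np.all(g_rows @ v >= h - settings.tolerance):
        return v

    gz = g_rows @ z
    gh = h - g_rows @ v0

    def fun(t):
        d = v0 + z @ t - anchor
        return float(np.sum(q * d * d))

    def jac(t):
        d = v0 + z @ t - anchor
        return 2.0 * z.T @ (q * d)

    res = minimize(
        fun, t_free, jac=jac, hess=lambda t: hess, method="trust-constr",
        constraints=[LinearConstraint(gz, gh, np.inf)],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000, "verbose": 0},
    )
    v = v0 + z @ res.x
    viol = gz @ res.x - gh
    if viol.size and viol.min() < -1e-6:
        bad = np.nonzero(viol < -1e-6)[0]
        raise RuntimeError(f"projection infeasible; violated inequality rows {bad.tolist()}")
    return v


def estimate_training_fluxes(
    network: ReactionNetwork,
    phenotypes: PhenotypeVector,
    reference_fluxes: np.ndarray,
    settings: QPSettings,
    genotype_indices: np.ndarray,
) -> FluxTable:
    """Stage (i): balanced fluxes for each training genotype.

    Anchored at the reference genotype's fluxes, with the biomass flux
    pinned to ``V_{ref,J} * Y_i / Y_ref`` as a hard equality.
    """
    ref = settings.reference_genotype_index
    if ref is None:
        raise ValueError("settings.reference_genotype_index is required")
    if not phenotypes.mask[ref]:
        raise ValueError("reference genotype has no observed phenotype")
    y_ref = phenotypes.values[ref]
    if y_ref == 0:
        raise ValueError("reference phenotype is zero; biomass ratio undefined")
    t = network.target_reaction_index
    irr_idx = np.nonzero(network.irreversible_mask)[0]
    ref_fluxes = np.asarray(reference_fluxes, dtype=float)
    # the training program carries only balance, nonnegativity and the
    # biomass ratio; the physiological box constraints apply to the
    # projection stage alone
    settings = QPSettings(**{**settings.__dict__, "use_additional_constraints": False,
                             "oxygenation_index": None, "carboxylation_index": None,
                             "sucrose_index": None, "starch_index": None})
    rows = []
    kept: list[int] = []
    for i in np.asarray(genotype_indices, dtype=int):
        if not phenotypes.mask[i]:
            raise ValueError(f"training genotype index {i} has no observed phenotype")
        m_i = network.coefficients_for(i)
        ratio_row = np.zeros(network.n_reactions)
        ratio_row[t] = 1.0
        eq_a = np.vstack([m_i, ratio_row])
        eq_b = np.concatenate([np.zeros(network.n_metabolites),
                               [ref_fluxes[t] * phenotypes.values[i] / y_ref]])
        try:
            rows.append(_solve_anchored_qp(ref_fluxes, eq_a, eq_b, irr_idx, settings))
        except RuntimeError as exc:
            # infeasible genotype: reported and skipped, the rest continue
            warnings.warn(f"training genotype index {i}: {exc}")
            continue
        kept.append(int(i))
    if not kept:
        raise RuntimeError("no training genotype admitted a feasible flux estimate")
    ids = [f"train{i}" for i in kept]
    return FluxTable(values=np.asarray(rows), genotype_ids=ids)


def predict_flux_genetics(
    training_fluxes: FluxTable,
    kinship: Kinship,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """Stage (ii): per-reaction GBLUP prediction of test-genotype fluxes.

    Reactions whose REML fit fails fall back to the training mean.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    k_tt = kinship.values[np.ix_(train_idx, train_idx)]
    out = np.empty((len(test_idx), training_fluxes.n_reactions))
    for j in range(training_fluxes.n_reactions):
        yj = training_fluxes.values[:, j]
        try:
            fit = reml_single_kernel(yj, k_tt)
            out[:, j] = gblup_predict(fit, kinship, train_idx, test_idx)
        except (ValueError, RuntimeError):
            out[:, j] = float(np.mean(yj))
    return out


def project_to_balance(
    u_row: np.ndarray,
    coefficients: np.ndarray,
    irreversible_mask: np.ndarray,
    settings: QPSettings,
) -> np.ndarray:
    """Stage (iii): min sum_j (V_j/U_j - 1)^2 s.t. M V = 0, V_j >= 0 on the
    irreversible set, plus the optional physiological box constraints."""
    u_row = np.asarray(u_row, dtype=float)
    m = np.atleast_2d(np.asarray(coefficients, dtype=float))
    irr_idx = np.nonzero(np.asarray(irreversible_mask, dtype=bool))[0]
    return _solve_anchored_qp(u_row, m, np.zeros(m.shape[0]), irr_idx, settings)


def qp_predict_pipeline(
    dataset: Dataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    settings: QPSettings,
) -> dict:
    """Chain the three stages for one CV fold.

    Returns ``{"predictions": array over test genotypes (biomass flux of
    the projected vector), "fluxes": projected test flux matrix,
    "training_fluxes": stage-(i) table, "failures": list}``.  Requires the
    dataset's reference fluxes (``true_fluxes`` row of the reference
    genotype).
    """
    if dataset.true_fluxes is None or dataset.reference_genotype_index is None:
        raise ValueError("dataset must carry reference fluxes and a reference genotype")
    settings = QPSettings(**{**settings.__dict__,
                             "reference_genotype_index": dataset.reference_genotype_index})
    ref_fluxes = dataset.true_fluxes.values[dataset.reference_genotype_index]
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    vt = estimate_training_fluxes(
        dataset.network, dataset.phenotypes, ref_fluxes, settings, train_idx
    )
    kept_train = np.array([int(g[5:]) for g in vt.genotype_ids], dtype=int)
    u_test = predict_flux_genetics(vt, dataset.kinship, kept_train, test_idx)
    t = dataset.network.target_reaction_index
    irr = dataset.network.irreversible_mask
    preds = np.full(len(test_idx), np.nan)
    fluxes = np.full((len(test_idx), dataset.network.n_reactions), np.nan)
    failures = []
    for pos, i in enumerate(test_idx):
        try:
            v = project_to_balance(u_test[pos], dataset.network.coefficients_for(i), irr, settings)
        except RuntimeError as exc:
            failures.append({"genotype_index": int(i), "error": str(exc)})
            continue
        fluxes[pos] = v
        preds[pos] = v[t]
    return {"predictions": preds, "fluxes": fluxes, "training_fluxes": vt, "failures": failures}
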