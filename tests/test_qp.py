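import numpy as np
import pytest

import fluxgp as fg
from fluxgp.qp import QPSettings, project_to_balance


def _grid_minimum(u, m, irr_mask, settings, span=6.0, steps=41):
    """Dense grid search over the nullspace of the balance constraints."""
    from scipy.linalg import null_space

    z = null_space(np.atleast_2d(m))
    q = 1.0 / np.maximum(np.abs(u), 1e-6) ** 2
    best_val, best_v = np.inf, None
    axes = [np.linspace(-span, span, steps)] * z.shape[1]
    for t in np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, z.shape[1]):
        v = z @ t
        if np.any(v[irr_mask] < -1e-9):
            continue
        if settings.use_additional_constraints:
            oxg, car = settings.oxygenation_index, settings.carboxylation_index
            lo, hi = settings.oxg_car_bounds
            if not (lo * v[oxg] - 1e-9 <= v[car] <= hi * v[oxg] + 1e-9):
                continue
            suc, sta = settings.sucrose_index, settings.starch_index
            lo2, hi2 = settings.suc_sta_bounds
            if not (lo2 * v[suc] - 1e-9 <= v[sta] <= hi2 * v[suc] + 1e-9):
                continue
        val = float(np.sum(q * (v - u) ** 2))
        if val < best_val:
            best_val, best_v = val, v
    return best_val, best_v


class TestProjectToBalance:
    def test_feasible_input_returned_unchanged(self):
        m = np.array([[1.0, -1.0]])
        u = np.array([2.0, 2.0])
        v = project_to_balance(u, m, np.array([True, True]), QPSettings())
        np.testing.assert_allclose(v, u, atol=1e-9)

    def test_hand_derived_two_reaction_minimizer(self):
        """Balance forces v1 = v2 = v; minimizing (v/2-1)^2 + (v/4-1)^2
        gives the stationary point v = 12/5."""
        m = np.array([[1.0, -1.0]])
        u = np.array([2.0, 4.0])
        v = project_to_balance(u, m, np.array([False, False]), QPSettings())
        np.testing.assert_allclose(v, [2.4, 2.4], atol=1e-6)

    def test_matches_grid_oracle_on_random_small_instances(self, rng):
        settings = QPSettings()
        for trial in range(10):
            j = int(rng.integers(3, 7))
            # keep the nullspace at <= 3 dims so the dense oracle stays small
            k = int(rng.integers(max(1, j - 3), j - 1))
            m = rng.integers(-2, 3, size=(k, j)).astype(float)
            m[np.count_nonzero(m, axis=1) == 0, 0] = 1.0
            u = rng.uniform(0.5, 4.0, size=j) * rng.choice([1.0, 1.0, -1.0], size=j)
            irr = rng.random(j) < 0.4
            u[irr] = np.abs(u[irr])
            v = project_to_balance(u, m, irr, settings)
            q = 1.0 / np.maximum(np.abs(u), 1e-6) ** 2
            obj = float(np.sum(q * (v - u) ** 2))
            grid_val, _ = _grid_minimum(u, m, irr, settings)
            assert obj <= grid_val + 1e-4
            assert np.abs(m @ v).max() < 1e-8
            if irr.any():
                assert v[irr].min() >= -1e-8

    def test_idempotent(self, rng):
        m = rng.integers(-2, 3, size=(2, 5)).astype(float)
        u = rng.uniform(0.5, 3.0, size=5)
        irr = np.array([True, False, True, False, True])
        v1 = project_to_balance(u, m, irr, QPSettings())
        v2 = project_to_balance(v1, m, irr, QPSettings())
        np.testing.assert_allclose(v2, v1, atol=1e-8)

    def test_additional_constraint_binds_on_boundary(self):
        """When the unconstrained optimum violates the carboxylation /
        oxygenation box, the solution sits on the box boundary and matches
        a dense grid search."""
        # reactions: oxg, car, two couplers; balance rows tie them loosely
        m = np.array([[1.0, 0.0, -1.0, 0.0],
                      [0.0, 1.0, 0.0, -1.0]])
        u = np.array([1.0, 8.0, 1.0, 8.0])  # car/oxg ratio 8 > 3.81
        settings = QPSettings(use_additional_constraints=True,
                              oxygenation_index=0, carboxylation_index=1,
                              sucrose_index=2, starch_index=3)
        v = project_to_balance(u, m, np.zeros(4, dtype=bool), settings)
        # balance aliases the two pairs (v0=v2, v1=v3), so the tighter
        # starch/sucrose upper bound 3.37 is the binding one
        assert v[3] == pytest.approx(3.37 * v[2], abs=1e-5)
        q = 1.0 / u ** 2
        obj = float(np.sum(q * (v - u) ** 2))
        grid_val, _ = _grid_minimum(u, m, np.zeros(4, bool), settings, span=10.0, steps=201)
        assert obj <= grid_val + 1e-3

    def test_infeasible_unique_point_rejected(self):
        # balance pins v = (c, c) with c < 0 while both reactions are irreversible
        m = np.array([[1.0, -1.0], [1.0, 1.0]])  # forces v1 = v2 and v1 = -v2 -> v = 0
        u = np.array([2.0, 2.0])
        v = project_to_balance(u, m, np.array([True, True]), QPSettings())
        np.testing.assert_allclose(v, 0.0, atol=1e-9)


class TestTrainingFluxes:
    def test_reference_genotype_reproduces_itself(self, small_dataset):
        ds = small_dataset
        ref = ds.reference_genotype_index
        settings = QPSettings(reference_genotype_index=ref)
        vt = fg.estimate_training_fluxes(
            ds.network, ds.phenotypes, ds.true_fluxes.values[ref], settings,
            np.array([ref]),
        )
        np.testing.assert_allclose(vt.values[0], ds.true_fluxes.values[ref], rtol=1e-5, atol=1e-6)

    def test_single_metabolite_ratio_solution(self):
        """Balance forces v1 = v2; the biomass ratio pins v2 = 3."""
        net = fg.ReactionNetwork(
            metabolite_ids=["A"], reaction_ids=["R1", "R2"],
            base_coefficients=np.array([[1.0, -1.0]]),
            reversible_set=frozenset({0}), irreversible_set=frozenset({1}),
            target_reaction_index=1,
        )
        ph = fg.PhenotypeVector(values=np.array([2.0, 3.0]), mask=np.array([True, True]))
        settings = QPSettings(reference_genotype_index=0)
        vt = fg.estimate_training_fluxes(net, ph, np.array([2.0, 2.0]), settings, np.array([1]))
        np.testing.assert_allclose(vt.values[0], [3.0, 3.0], atol=1e-8)

    def test_training_solutions_balance(self, small_dataset):
        ds = small_dataset
        settings = QPSettings(reference_genotype_index=ds.reference_genotype_index)
        idx = np.arange(8)
        vt = fg.estimate_training_fluxes(
            ds.network, ds.phenotypes,
            ds.true_fluxes.values[ds.reference_genotype_index], settings, idx,
        )
        for pos, i in enumerate(idx):
            m_i = ds.network.coefficients_for(i)
            assert np.abs(m_i @ vt.values[pos]).max() < 1e-6


class TestPipeline:
    def test_predictions_come_from_balanced_fluxes(self, small_dataset):
        ds = small_dataset
        train = np.arange(16)
        test = np.arange(16, 24)
        out = fg.qp_predict_pipeline(ds, train, test, QPSettings())
        assert out["predictions"].shape == (8,)
        assert np.isfinite(out["predictions"]).all()
        for pos, i in enumerate(test):
            m_i = ds.network.coefficients_for(i)
            assert np.abs(m_i @ out["fluxes"][pos]).max() < 1e-6

    def test_flux_prediction_shape_and_fallback(self, small_dataset):
        ds = small_dataset
        train, test = np.arange(16), np.arange(16, 24)
        settings = QPSettings(reference_genotype_index=ds.reference_genotype_index)
        vt = fg.estimate_training_fluxes(
            ds.network, ds.phenotypes,
            ds.true_fluxes.values[ds.reference_genotype_index], settings, train,
        )
        u = fg.predict_flux_genetics(vt, ds.kinship, train, test)
        assert u.shape == (8, ds.network.n_reactions)
        # constant training fluxes for one reaction -> prediction collapses
        # to that constant (mean fallback path)
        vt.values[:, 2] = 5.0
        u2 = fg.predict_flux_genetics(vt, ds.kinship, train, test)
        np.testing.assert_allclose(u2[:, 2], 5.0, atol=1e-6)

    def test_test_phenotypes_never_leak(self, small_dataset):
        """Perturbing held-out phenotypes leaves QP predictions unchanged."""
        import copy

        ds = small_dataset
        train, test = np.arange(16), np.arange(16, 24)
        out1 = fg.qp_predict_pipeline(ds, train, test, QPSettings())
        ds2 = copy.deepcopy(ds)
        ds2.phenotypes.values[test] += 123.4
        out2 = fg.qp_predict_pipeline(ds2, train, test, QPSettings())
        np.testing.assert_array_equal(out1["predictions"], out2["predictions"])
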