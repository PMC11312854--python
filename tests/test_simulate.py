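import numpy as np
import pytest

import fluxgp as fg
from fluxgp.mixedmodel import GeneticParams
from fluxgp.simulate import sample_reaction_params, simulate_network, simulate_snps


def _config(**kw):
    base = dict(n_genotypes=20, n_markers=300, n_metabolites=8, n_reactions=10,
                metabolites_per_reaction=3, seed=42)
    base.update(kw)
    return fg.SimulationConfig(**base)


class TestSnps:
    def test_deterministic_given_seed(self):
        cfg = _config()
        a = simulate_snps(cfg, np.random.default_rng(5))
        b = simulate_snps(cfg, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_dosages_in_range(self):
        x = simulate_snps(_config(), np.random.default_rng(0))
        assert set(np.unique(x)) <= {0, 1, 2}

    def test_maf_pinned_at_half(self):
        cfg = _config(maf_min=0.5, maf_max=0.5, n_genotypes=400, n_markers=200,
                      cluster_mix=1.0)
        x = simulate_snps(cfg, np.random.default_rng(1))
        freqs = x.mean(axis=0) / 2
        assert abs(freqs.mean() - 0.5) < 0.02

    def test_grm_from_default_panel_is_psd(self):
        cfg = _config(n_genotypes=67, n_markers=2000)
        x = simulate_snps(cfg, np.random.default_rng(2))
        g = fg.vanraden_grm(x)
        assert np.linalg.eigvalsh(g.values)[0] >= 0.0


class TestNetwork:
    def test_generated_network_is_valid(self):
        net = simulate_network(_config(), np.random.default_rng(3))
        assert fg.validate_network(net) == []

    def test_sparsity_medians_within_one(self):
        cfg = fg.SimulationConfig(n_genotypes=10, n_markers=50, n_metabolites=30,
                                  n_reactions=36, seed=0)
        net = simulate_network(cfg, np.random.default_rng(4))
        col_deg = np.count_nonzero(net.base_coefficients, axis=0)
        row_deg = np.count_nonzero(net.base_coefficients, axis=1)
        assert abs(np.median(col_deg) - 4) <= 1
        assert abs(np.median(row_deg) - 2) <= 1

    def test_every_metabolite_touches_two_reactions(self):
        net = simulate_network(_config(), np.random.default_rng(5))
        assert np.count_nonzero(net.base_coefficients, axis=1).min() >= 2

    def test_infeasible_sparsity_rejected(self):
        cfg = _config(n_metabolites=3, n_reactions=4, metabolites_per_reaction=4)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_network(cfg, np.random.default_rng(6))

    def test_target_reaction_consumes_and_is_irreversible(self):
        net = simulate_network(_config(), np.random.default_rng(7))
        t = net.target_reaction_index
        col = net.base_coefficients[:, t]
        assert col[col != 0].max() < 0
        assert t in net.irreversible_set


class TestFluxes:
    def test_last_coefficient_adjustment_formula(self):
        """One metabolite with entries at reactions 1 and 2 and last entry 3:
        coefficients (1, 1) and fluxes (2, 3, 5) force the last coefficient
        to (0 - 1*2 - 1*3)/5 = -1, balancing the row exactly."""
        net = fg.ReactionNetwork(
            metabolite_ids=["A"], reaction_ids=["R1", "R2", "R3"],
            base_coefficients=np.array([[1.0, 1.0, -0.3]]),
            reversible_set=frozenset(), irreversible_set=frozenset({0, 1, 2}),
            target_reaction_index=2,
        )
        kin = fg.Kinship(values=np.eye(1), genotype_ids=["g1"])
        params = GeneticParams(mu=[2.0, 3.0, 5.0], sigma2_u=[1e-12] * 3, sigma2_v=[1e-12] * 3)
        fluxes, adjusted, _ = fg.simulate_fluxes(net, kin, params, np.random.default_rng(0))
        np.testing.assert_allclose(fluxes.values[0], [2.0, 3.0, 5.0], atol=1e-4)
        coef = adjusted.genotype_overrides[(0, 0, 2)]
        v = fluxes.values[0]
        assert coef == pytest.approx((0 - v[0] - v[1]) / v[2])
        assert np.abs(fg.balance_residuals(adjusted, fluxes)).max() < 1e-10

    def test_zero_residual_variance_collapses_v_to_u(self, small_dataset):
        net = small_dataset.network
        base = fg.ReactionNetwork(
            metabolite_ids=net.metabolite_ids, reaction_ids=net.reaction_ids,
            base_coefficients=net.base_coefficients,
            reversible_set=net.reversible_set, irreversible_set=net.irreversible_set,
            target_reaction_index=net.target_reaction_index,
        )
        j = net.n_reactions
        params = GeneticParams(mu=np.full(j, 10.0), sigma2_u=np.full(j, 1.0),
                               sigma2_v=np.zeros(j))
        fluxes, _, u = fg.simulate_fluxes(base, small_dataset.kinship, params,
                                          np.random.default_rng(1))
        np.testing.assert_allclose(fluxes.values, u, atol=1e-12)

    def test_irreversible_fluxes_nonnegative(self, small_dataset):
        irr = small_dataset.network.irreversible_mask
        assert small_dataset.true_fluxes.values[:, irr].min() >= 0.0

    def test_heritability_recovered_at_large_n(self):
        cfg = fg.SimulationConfig(n_genotypes=240, n_markers=1500, n_metabolites=8,
                                  n_reactions=10, metabolites_per_reaction=3,
                                  irreversible_fraction=0.0, seed=9)
        rng = np.random.default_rng(11)
        snps = simulate_snps(cfg, rng)
        kin = fg.vanraden_grm(snps)
        net = simulate_network(cfg, rng)
        j = net.n_reactions
        h2 = 0.7
        params = GeneticParams(mu=np.full(j, 20.0), sigma2_u=np.full(j, h2 * 4.0),
                               sigma2_v=np.full(j, (1 - h2) * 4.0))
        fluxes, _, u = fg.simulate_fluxes(net, kin, params, rng)
        # genetic variance realized through G; compare genetic share per reaction
        var_u = u.var(axis=0, ddof=1)
        ratio = var_u / (var_u + params.sigma2_v)
        assert abs(np.median(ratio) - h2) < 0.12


class TestPhenotypes:
    def test_noise_variance_fraction(self):
        rng = np.random.default_rng(21)
        target = rng.normal(50.0, 2.0, size=10_000)
        fluxes = fg.FluxTable(values=target[:, None], genotype_ids=[f"g{i}" for i in range(10_000)])
        ph = fg.simulate_phenotypes(fluxes, 0, 0.25, np.random.default_rng(22))
        realized = np.var(ph.values - target, ddof=1) / np.var(target, ddof=1)
        assert realized == pytest.approx(0.25, abs=0.02)

    def test_vanishing_noise_returns_target_flux(self):
        fluxes = fg.FluxTable(values=np.arange(1.0, 11.0)[:, None],
                              genotype_ids=[f"g{i}" for i in range(10)])
        ph = fg.simulate_phenotypes(fluxes, 0, 1e-12, np.random.default_rng(0))
        np.testing.assert_allclose(ph.values, fluxes.values[:, 0], atol=1e-4)

    def test_constant_target_rejected(self):
        fluxes = fg.FluxTable(values=np.full((5, 1), 3.0), genotype_ids=list("abcde"))
        with pytest.raises(ValueError, match="variance"):
            fg.simulate_phenotypes(fluxes, 0, 0.25, np.random.default_rng(0))


class TestGenerateDataset:
    def test_deterministic_given_config_and_seed(self, tmp_path):
        cfg = _config()
        d1 = fg.generate_dataset(cfg)
        d2 = fg.generate_dataset(cfg)
        assert np.array_equal(d1.true_fluxes.values, d2.true_fluxes.values)
        assert np.array_equal(d1.phenotypes.values, d2.phenotypes.values)
        p1 = fg.save_dataset(d1, tmp_path / "a")
        p2 = fg.save_dataset(d2, tmp_path / "b")
        for name in ("network.tsv", "kinship.tsv", "phenotypes.tsv", "fluxes.tsv"):
            assert (p1 / name).read_text() == (p2 / name).read_text()

    def test_replicates_have_distinct_seeds(self):
        reps = fg.generate_replicates(_config(), n_replicates=4)
        seeds = [r.metadata["seed"] for r in reps]
        assert len(set(seeds)) == 4
        assert [r.metadata["replicate"] for r in reps] == [0, 1, 2, 3]

    def test_generated_dataset_valid_and_balanced(self, small_dataset):
        assert fg.validate_network(small_dataset.network) == []
        res = fg.balance_residuals(small_dataset.network, small_dataset.true_fluxes)
        assert np.abs(res).max() < 1e-8

    def test_default_sample_params_span_two_orders(self):
        params = sample_reaction_params(300, np.random.default_rng(0))
        assert params.mu.min() >= 1.0 and params.mu.max() <= 100.0
        h2 = params.sigma2_u / (params.sigma2_u + params.sigma2_v)
        assert 0.5 <= h2.min() and h2.max() <= 0.9
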