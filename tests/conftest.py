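import numpy as np
import pytest

import fluxgp as fg


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by read-only tests."""
    cfg = fg.SimulationConfig(
        n_genotypes=24, n_markers=600, n_metabolites=8, n_reactions=10,
        metabolites_per_reaction=3, seed=101,
    )
    return fg.generate_dataset(cfg)


@pytest.fixture()
def tiny_network():
    """Two metabolites, two reactions, hand-checkable."""
    return fg.ReactionNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["R1", "R2"],
        base_coefficients=np.array([[1.0, -1.0], [-1.0, 1.0]]),
        reversible_set=frozenset({0}),
        irreversible_set=frozenset({1}),
        target_reaction_index=1,
    )
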