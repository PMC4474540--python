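import numpy as np
import pytest

from dysreg.simulate import SimConfig, generate


def tiny_config(seed: int = 0, **overrides) -> SimConfig:
    """A small but fully featured simulation config for structural tests."""
    base = dict(
        n_cohorts=3,
        n_genes=300,
        n_pairs=10,
        category_sizes={
            "TF": 30, "RBP": 40, "lncRNA": 10, "allOnco": 40,
            "COSMIC_frameshift": 10,
        },
        tissue_set_size=20,
        pathway_sizes={"pw_a": 15, "pw_b": 15},
        n_hub_rbps=2,
        hub_neighbor_count=10,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_sim():
    return generate(tiny_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
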