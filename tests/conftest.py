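import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from igrep.germline import load_toy_reference
from igrep.simulate import SimulationConfig, SubsetConfig, default_config


@pytest.fixture(scope="session")
def ref():
    return load_toy_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def uniform_vfam():
    return {f"IGHV{i}": 0.2 for i in range(1, 6)}


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A reduced two-subset config for fast end-to-end tests."""
    cfg = SimulationConfig(
        seed=seed,
        subject="T1",
        subsets={
            "N": SubsetConfig(
                n_clones=40,
                clone_size_law=("zeta", {"a": 2.5, "max_size": 30}),
                shm_rate=0.0,
                isotype_probs={"IgD": 0.5, "IgM": 0.5, "IgG": 0.0, "IgA": 0.0},
            ),
            "M": SubsetConfig(
                n_clones=40,
                clone_size_law=("zeta", {"a": 2.0, "max_size": 60}),
                shm_rate=0.05,
                isotype_probs={"IgD": 0.0, "IgM": 0.2, "IgG": 0.5, "IgA": 0.3},
            ),
        },
        reads_per_molecule_law=("constant", {"n": 6}),
        per_base_read_error=0.0,
        low_q_fraction=0.0,
        retention_fraction=0.05,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture()
def tiny_cohort_config():
    return small_config(11)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(3)
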