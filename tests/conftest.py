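import numpy as np
import pytest

from mrrbayes import MRRDataset, PriorSet, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def study1_cfg() -> SimulationConfig:
    """Reference simulation-study conditions (the package defaults)."""
    return SimulationConfig(seed=20240901)


@pytest.fixture(scope="session")
def study1_dataset(study1_cfg) -> "MRRDataset":
    return simulate_dataset(study1_cfg)


@pytest.fixture(scope="session")
def priors() -> PriorSet:
    return PriorSet()


@pytest.fixture()
def tiny_dataset() -> MRRDataset:
    return MRRDataset(
        m=np.array([5, 3, 1]),
        u=np.array([12, 9, 11]),
        N=50,
        n_pupae=8,
        f_a=0.2,
    )
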