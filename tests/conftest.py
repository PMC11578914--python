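import numpy as np
import pytest

from ordinvar.model import OrdinalFactorModel
from ordinvar.simulate import build_spec, simulate_dataset

RESID_PAIRS = [(2, 3)]


@pytest.fixture(scope="session")
def invariant_spec():
    """Fully invariant 4-group DGP at the emulated survey's conditions."""
    return build_spec(n_groups=4, n_per_group=2000, missing_rate=0.055)


@pytest.fixture(scope="session")
def invariant_dataset(invariant_spec):
    return simulate_dataset(invariant_spec, seed=42)


@pytest.fixture(scope="session")
def multigroup_model(invariant_dataset):
    return OrdinalFactorModel(invariant_dataset, resid_pairs=RESID_PAIRS)


@pytest.fixture(scope="session")
def single_group_dataset():
    spec = build_spec(n_groups=1, n_per_group=5000)
    return simulate_dataset(spec, seed=7)


@pytest.fixture(scope="session")
def single_group_fit(single_group_dataset):
    model = OrdinalFactorModel(single_group_dataset, resid_pairs=RESID_PAIRS)
    return model.fit(level="configural")
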