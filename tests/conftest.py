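import numpy as np
import pytest

from aecnet import SyntheticSpec, generate_source_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mixed_null_subject():
    """One subject with strong leakage (mixing 0.5) and no planted
    coupling — shared by the leakage-oriented connectivity tests."""
    spec = SyntheticSpec(
        n_nodes=20,
        n_subjects_per_group=1,
        n_trials=10,
        band="beta",
        mixing_strength=0.5,
        coupling_by_group={"A": 0.0, "B": 0.0},
        seed=1,
    )
    subjects, truth = generate_source_dataset(spec)
    return subjects[0], truth
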