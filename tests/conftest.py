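import pytest

from bpnet.labels import build_labeled_arrays
from bpnet.model import ModelConfig
from bpnet.synth import SimConfig, make_dataset


@pytest.fixture(scope="session")
def desk_dataset():
    """The desk-scale study cohort: 40 records x 50 s -> ~200 segments."""
    return make_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def labeled_splits(desk_dataset):
    return {
        name: build_labeled_arrays(desk_dataset.split(name))
        for name in ("train", "val", "test")
    }


@pytest.fixture
def tiny_model_cfg():
    """A model small enough for finite-difference gradient checks."""
    return ModelConfig(
        seq_len=4, step_dim=5, hidden_size=3, head_hidden_1=6, head_hidden_2=3
    )
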