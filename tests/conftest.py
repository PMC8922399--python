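import numpy as np
import pytest

from mtqsar.graphs import FeatureSchema
from mtqsar.synthetic import FixtureSpec, make_fixture_dataset
from mtqsar.training import GraphDataset, TrainConfig, train
from mtqsar.network import MTModelConfig


@pytest.fixture(scope="session")
def schema():
    return FeatureSchema()


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small synthetic 4-target dataset with planted effects."""
    spec = FixtureSpec(n_molecules=60, seed=42)
    records, data = make_fixture_dataset(spec)
    return spec, records, data


@pytest.fixture(scope="session")
def tiny_dataset(tiny_fixture):
    spec, records, _ = tiny_fixture
    return GraphDataset(records, list(spec.targets))


@pytest.fixture(scope="session")
def tiny_trained(tiny_dataset):
    """A briefly trained small model shared by interpretation tests."""
    spec_targets = tuple(tiny_dataset.targets)
    mc = MTModelConfig(targets=spec_targets, graph_feat_size=24,
                       dropout=0.0, seed=7)
    tc = TrainConfig(learning_rate=3e-3, batch_size=48, max_epochs=15,
                     patience=14, seed=7)
    state, hist = train(tiny_dataset, mc, tc)
    return state, hist
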