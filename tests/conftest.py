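import pytest

from p31shift import apply_scaler, build_graphs, gen_toy_dataset, make_splits
from p31shift.model import SDGNNConfig
from p31shift.train import TrainConfig, train_model


@pytest.fixture(scope="session")
def toy_dataset():
    """400 synthetic increment-model records across all six parent classes."""
    return gen_toy_dataset(400, seed=11)


@pytest.fixture(scope="session")
def toy_graphs(toy_dataset):
    graphs, skipped = build_graphs(toy_dataset.records)
    assert not skipped
    return graphs


@pytest.fixture(scope="session")
def toy_split(toy_dataset):
    return make_splits(toy_dataset.records, "smiles_group", n_folds=1, seed=3)[0]


@pytest.fixture(scope="session")
def trained(toy_graphs, toy_split):
    """A small model trained on the toy data, with its held-out test graphs."""
    tcfg = TrainConfig(lr=0.01, wd=0.0, bs=32, patience=15, epochs=60, seed=3)
    mcfg = SDGNNConfig(hidden_dim=32, seed=3)
    model, history = train_model(toy_graphs, toy_split, tcfg, mcfg)
    test_graphs = [g for g in toy_graphs if toy_split.assignment[g.record_id] == "test"]
    return model, history, test_graphs


@pytest.fixture()
def scaled_test_graphs(trained):
    model, _, test_graphs = trained
    return [apply_scaler(g, model.scaler) for g in test_graphs]
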