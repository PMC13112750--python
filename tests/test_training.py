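import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p31shift import ShiftRecord, build_graphs, gen_toy_dataset, mae, rmse
from p31shift.model import SDGNNConfig
from p31shift.train import (
    DEFAULT_GRID,
    MetricsReport,
    SplitPlan,
    TrainConfig,
    _fit,
    evaluate,
    grid_search,
    make_splits,
    subsample,
    train_model,
)


# --- metrics -------------------------------------------------------------------

def test_mae_hand_values():
    assert mae([1, 2], [1, 2]) == 0.0
    assert mae([0], [3]) == 3.0
    assert mae([10, 20, 40], [12, 17, 44]) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        mae([1], [1, 2])
    with pytest.raises(ValueError):
        mae([], [])


def test_rmse_hand_values():
    assert rmse([0], [3]) == 3.0
    assert rmse([0, 0], [3, 1]) == pytest.approx(math.sqrt(5.0))


@settings(deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=1, max_size=30),
    st.integers(0, 2**31 - 1),
)
def test_rmse_dominates_mae(y, seed):
    rng = np.random.default_rng(seed)
    yhat = np.asarray(y) + rng.normal(size=len(y))
    assert rmse(y, yhat) >= mae(y, yhat) - 1e-12


# --- subsampling -----------------------------------------------------------------

def test_subsample_identity_and_reproducibility(toy_dataset):
    records = toy_dataset.records
    assert subsample(records, len(records), seed=1) == records
    a = subsample(records, 50, seed=2)
    b = subsample(records, 50, seed=2)
    assert a == b and len(a) == 50
    with pytest.raises(ValueError):
        subsample(records, len(records) + 1, seed=0)


def test_subsample_is_uniform():
    records = [ShiftRecord(f"r{i}", "CP", 0.0) for i in range(1000)]
    hits = np.zeros(1000)
    n_rep = 1000
    for rep in range(n_rep):
        for rec in subsample(records, 100, seed=rep):
            hits[int(rec.record_id[1:])] += 1
    freq = hits / n_rep
    # binomial(n_rep=1000, p=0.1) per record; 5 sigma keeps the expected number
    # of false alarms across 1000 records far below one
    sigma = math.sqrt(0.1 * 0.9 / n_rep)
    assert np.all(np.abs(freq - 0.1) < 5 * sigma)
    assert abs(freq.mean() - 0.1) < 1e-12


# --- splits ----------------------------------------------------------------------

def test_duplicate_smiles_always_co_assigned():
    records = [ShiftRecord(f"r{i}", s, float(i)) for i, s in
               enumerate(["CP", "PC", "CCP", "PCC", "CP(C)C"] + [f"{'C'*k}P" for k in range(3, 9)])]
    for plan in make_splits(records, "smiles_group", n_folds=5, seed=0):
        assert plan.assignment["r0"] == plan.assignment["r1"]  # CP == PC
        assert plan.assignment["r2"] == plan.assignment["r3"]  # CCP == PCC


def test_scaffold_split_keeps_scaffolds_together():
    rings = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCNCC1", "c1ccsc1",
             "C1CCOC1", "c1ccoc1", "C1CCCC1", "c1ccc2ccccc2c1", "C1CCNC1"]
    records = [
        ShiftRecord(f"s{i}_{j}", f"{ring}{'C'*j}P", float(i))
        for i, ring in enumerate(rings)
        for j in range(1, 11)
    ]
    from p31shift.train import scaffold_label
    labels = {r.record_id: scaffold_label(r.smiles) for r in records}
    assert len(set(labels.values())) == 10
    for plan in make_splits(records, "scaffold", n_folds=3, seed=1):
        parts_per_scaffold = {}
        for rid, part in plan.assignment.items():
            parts_per_scaffold.setdefault(labels[rid], set()).add(part)
        assert all(len(parts) == 1 for parts in parts_per_scaffold.values())


def test_split_ratios_at_group_level():
    records = [ShiftRecord(f"r{i}", f"{'C'*i}P", float(i)) for i in range(1, 101)]
    plan = make_splits(records, "smiles_group", n_folds=1, seed=0)[0]
    sizes = {part: len(plan.ids(part)) for part in ("train", "val", "test")}
    assert sizes == {"train": 80, "val": 10, "test": 10}


def test_split_requires_three_groups():
    records = [ShiftRecord("a", "CP", 0.0), ShiftRecord("b", "CCP", 1.0)]
    with pytest.raises(ValueError):
        make_splits(records, "smiles_group", n_folds=1, seed=0)


def test_leakage_guard_on_fixture_corpus():
    from p31shift.io import canonical_smiles
    from p31shift.train import scaffold_label

    # ring-containing variant so scaffold grouping is non-degenerate
    corpus = gen_toy_dataset(300, seed=7, ring_fraction=0.3)
    for mode in ("smiles_group", "scaffold"):
        label_fn = canonical_smiles if mode == "smiles_group" else scaffold_label
        labels = {r.record_id: label_fn(r.smiles) for r in corpus.records}
        for plan in make_splits(corpus.records, mode, n_folds=4, seed=7):
            by_part = {p: set() for p in ("train", "val", "test")}
            for rid, part in plan.assignment.items():
                by_part[part].add(labels[rid])
            assert not (by_part["train"] & by_part["val"])
            assert not (by_part["train"] & by_part["test"])
            assert not (by_part["val"] & by_part["test"])


# --- training ---------------------------------------------------------------------

def test_zero_learning_rate_stops_after_patience(toy_graphs, toy_split):
    tcfg = TrainConfig(lr=0.0, wd=0.0, bs=32, patience=5, epochs=100, seed=0)
    model, hist = train_model(toy_graphs, toy_split, tcfg, SDGNNConfig(hidden_dim=8, seed=0))
    assert len(hist["val_mae"]) == tcfg.patience + 1
    assert len(set(hist["val_mae"])) == 1  # flat history: weights never move
    assert hist["best_epoch"] == 1


def test_training_beats_constant_mean_baseline(trained, toy_graphs, toy_split):
    model, hist, test_graphs = trained
    train_y = [g.y for g in toy_graphs if toy_split.assignment[g.record_id] == "train"]
    y = np.array([g.y for g in test_graphs])
    model_mae = mae(y, model.predict(test_graphs))
    baseline_mae = mae(y, np.full_like(y, np.mean(train_y)))
    assert model_mae < 0.5 * baseline_mae


def test_early_stopping_restores_best_epoch(trained, toy_graphs, toy_split):
    model, hist, _ = trained
    val_graphs = [g for g in toy_graphs if toy_split.assignment[g.record_id] == "val"]
    y = np.array([g.y for g in val_graphs])
    restored_val_mae = mae(y, model.predict(val_graphs))
    assert restored_val_mae == pytest.approx(min(hist["val_mae"]), abs=1e-9)


def test_training_is_deterministic(toy_graphs, toy_split):
    tcfg = TrainConfig(lr=0.01, wd=0.0001, bs=16, patience=5, epochs=8, seed=4)
    mcfg = SDGNNConfig(hidden_dim=8, seed=4)
    _, h1 = train_model(toy_graphs, toy_split, tcfg, mcfg)
    _, h2 = train_model(toy_graphs, toy_split, tcfg, mcfg)
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_mae"] == h2["val_mae"]


def test_parameter_recovery_improves_with_training_size():
    # noise-free increment fixtures: held-out error decreases with n
    maes = []
    for n in (50, 200, 1000):
        toy = gen_toy_dataset(n, seed=21, noise_sd=0.0)
        graphs, _ = build_graphs(toy.records)
        split = __import__("p31shift").make_splits(toy.records, "smiles_group", 1, seed=21)[0]
        tcfg = TrainConfig(lr=0.01, wd=0.0, bs=32, patience=15, epochs=40, seed=21)
        model, _ = train_model(graphs, split, tcfg, SDGNNConfig(hidden_dim=32, seed=21))
        test = [g for g in graphs if split.assignment[g.record_id] == "test"]
        maes.append(mae([g.y for g in test], model.predict(test)))
    assert maes[0] > maes[1] > maes[2]


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_divergence_raises_diagnostic(toy_graphs, toy_split):
    # an absurd learning rate overflows the activations within a few epochs
    tcfg = TrainConfig(lr=1e80, wd=0.0, bs=16, patience=5, epochs=10, seed=0)
    with pytest.raises(RuntimeError, match="diverged"):
        train_model(toy_graphs, toy_split, tcfg, SDGNNConfig(hidden_dim=8, seed=0))


# --- grid search -------------------------------------------------------------------

def test_grid_search_single_combination(toy_graphs):
    grid = {"lr": [0.01], "wd": [0.0], "bs": [32], "hd": [16], "patience": [5]}
    losses = {}
    def mock(tr, va, tcfg, mcfg):
        return 1.0
    tcfg, mcfg, results = grid_search(grid, toy_graphs[:12], train_fn=mock)
    assert (tcfg.lr, tcfg.wd, tcfg.bs, mcfg.hidden_dim, tcfg.patience) == (0.01, 0.0, 32, 16, 5)
    assert len(results) == 1


def test_grid_search_selects_argmin_with_mock_losses(toy_graphs):
    grid = {"lr": [0.01, 0.001], "wd": [0.0], "bs": [16, 32], "hd": [16, 32], "patience": [5]}
    preset = {(0.001, 0.0, 32, 16, 5): 0.5}
    def mock(tr, va, tcfg, mcfg):
        return preset.get((tcfg.lr, tcfg.wd, tcfg.bs, mcfg.hidden_dim, tcfg.patience), 2.0)
    tcfg, mcfg, results = grid_search(grid, toy_graphs[:12], train_fn=mock)
    assert (tcfg.lr, tcfg.bs, mcfg.hidden_dim) == (0.001, 32, 16)
    assert len(results) == 8


def test_grid_search_tie_break_prefers_cheap_models(toy_graphs):
    grid = {"lr": [0.01, 0.001], "wd": [0.0], "bs": [16, 32], "hd": [16, 32], "patience": [5]}
    def mock(tr, va, tcfg, mcfg):
        return 1.0  # all tied
    tcfg, mcfg, _ = grid_search(grid, toy_graphs[:12], train_fn=mock)
    # smaller hd, then larger bs, then lower lr
    assert (mcfg.hidden_dim, tcfg.bs, tcfg.lr) == (16, 32, 0.001)


def test_default_grid_has_144_combinations(toy_graphs):
    calls = []
    def mock(tr, va, tcfg, mcfg):
        calls.append(1)
        return 1.0
    _, _, results = grid_search(DEFAULT_GRID, toy_graphs[:12], n_cv_folds=3, train_fn=mock)
    assert len(results) == 3 * 2 * 3 * 4 * 2 == 144
    assert len(calls) == 144 * 3


def test_grid_search_invariant_to_enumeration_order(toy_graphs):
    grid = {"lr": [0.01, 0.001], "wd": [0.0, 0.0001], "bs": [16, 32], "hd": [16, 32], "patience": [5]}
    rev = {k: list(reversed(v)) for k, v in grid.items()}
    def mock(tr, va, tcfg, mcfg):
        return float(tcfg.lr * 100 + mcfg.hidden_dim / 64)
    a = grid_search(grid, toy_graphs[:12], train_fn=mock)
    b = grid_search(rev, toy_graphs[:12], train_fn=mock)
    assert (a[0], a[1]) == (b[0], b[1])


# --- evaluation --------------------------------------------------------------------

class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, graphs, scaled=False):
        return np.full(len(graphs), self.value)


def test_evaluate_fold_aggregation(toy_graphs):
    graphs = toy_graphs[:10]
    y = np.array([g.y for g in graphs])
    # two constant predictors with offsets 8 and 10 from the truth
    folds = [(_ConstantModel(float(v)), graphs) for v in (y.mean(),)]
    # hand-constructed fold MAEs [8, 10] -> 9 ± 1 (population std)
    report = MetricsReport(fold_mae=[8.0, 10.0], fold_rmse=[9.0, 12.0], n_per_fold=[5, 5])
    assert report.mean_mae == 9.0 and report.std_mae == 1.0


def test_evaluate_single_fold_and_metric_ordering(trained):
    model, _, test_graphs = trained
    report = evaluate([(model, test_graphs)])
    assert report.std_mae == 0.0  # one fold
    assert report.fold_rmse[0] >= report.fold_mae[0]
    assert report.quantiles[0]["q50"] <= report.quantiles[0]["q95"]
    with pytest.raises(ValueError):
        evaluate([])
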