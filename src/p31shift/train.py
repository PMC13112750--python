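"""Training protocol: metrics, grouped splits, early stopping, grid search.

Evaluation follows a molecule-disjoint protocol: records are grouped either by
canonical SMILES (identical structures never span partitions) or by
Bemis–Murcko scaffold (closely related ring systems never span partitions),
and each fold is an independent 80/10/10 train/validation/test partition at
the group level. The MAE (ppm) is both the training loss and the headline
metric; fold statistics are reported as mean ± population standard deviation.
"""

from __future__ import annotations

import copy
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.model_selection import KFold

from .featurize import MolGraph, ScalerParams, apply_scaler, fit_scaler
from .io import ShiftRecord, canonical_smiles
from .model import AdamW, Batch, Params, SDGNNConfig, backward, count_parameters, forward, init_model, make_batch

logger = logging.getLogger(__name__)

#: hyperparameter grid used for exhaustive search (144 combinations)
DEFAULT_GRID = {
    "lr": [0.01, 0.001, 0.0001],
    "wd": [0.0, 0.0001],
    "bs": [16, 32, 48],
    "hd": [32, 64, 128, 256],
    "patience": [40, 200],
}

DATASET_SIZES = (100, 500, 1000, 2500, 5000, 14062)


# --- metrics ------------------------------------------------------------------

def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y, yhat = np.asarray(y, dtype=np.float64), np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length 1-D sequences")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error, (1/N)·Σ|yᵢ − ŷᵢ|."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root mean squared error, √((1/N)·Σ(yᵢ − ŷᵢ)²)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


# --- splits -------------------------------------------------------------------

@dataclass
class SplitPlan:
    """One molecule-disjoint 80/10/10 partition at the group level."""

    mode: str                      # "smiles_group" | "scaffold"
    assignment: dict[str, str]     # record_id -> "train" | "val" | "test"
    fold: int
    seed: int
    k: int

    def ids(self, part: str) -> list[str]:
        return [rid for rid, p in self.assignment.items() if p == part]


def scaffold_label(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES; acyclic molecules share the empty scaffold."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)


def subsample(records: list[ShiftRecord], k: int, seed: int) -> list[ShiftRecord]:
    """Uniform random subset of size k, drawn before splitting; seeded."""
    if k > len(records):
        raise ValueError(f"k={k} exceeds dataset size {len(records)}")
    idx = np.random.default_rng(seed).choice(len(records), size=k, replace=False)
    return [records[i] for i in sorted(idx)]


def make_splits(
    records: list[ShiftRecord], mode: str = "smiles_group", n_folds: int = 10, seed: int = 0
) -> list[SplitPlan]:
    """n_folds independent repeated grouped 80/10/10 splits (seeds seed..seed+n−1)."""
    if mode == "smiles_group":
        labels = {r.record_id: canonical_smiles(r.smiles) for r in records}
    elif mode == "scaffold":
        labels = {r.record_id: "scaffold:" + scaffold_label(r.smiles) for r in records}
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    groups = sorted(set(labels.values()))
    if len(groups) < 3:
        raise ValueError("need at least 3 groups to form train/val/test partitions")

    plans = []
    for fold in range(n_folds):
        rng = np.random.default_rng(seed + fold)
        order = [groups[i] for i in rng.permutation(len(groups))]
        n_train = int(0.8 * len(groups))
        n_val = max(1, int(0.1 * len(groups)))
        n_train = max(1, min(n_train, len(groups) - n_val - 1))
        part_of = {}
        for j, grp in enumerate(order):
            part_of[grp] = "train" if j < n_train else ("val" if j < n_train + n_val else "test")
        assignment = {rid: part_of[lab] for rid, lab in labels.items()}
        plan = SplitPlan(mode, assignment, fold, seed + fold, k=len(records))
        _assert_no_leakage(plan, labels)
        plans.append(plan)
    return plans


def _assert_no_leakage(plan: SplitPlan, labels: dict[str, str]) -> None:
    seen: dict[str, str] = {}
    for rid, part in plan.assignment.items():
        lab = labels[rid]
        if lab in seen and seen[lab] != part:
            raise AssertionError(f"group {lab!r} spans partitions {seen[lab]}/{part}")
        seen[lab] = part


# --- training -----------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 0.01
    wd: float = 0.0
    bs: int = 32
    patience: int = 200
    epochs: int = 500
    seed: int = 0

    def validate_grid(self, grid: dict | None = None) -> None:
        grid = grid or DEFAULT_GRID
        for name in ("lr", "wd", "bs", "patience"):
            if getattr(self, name) not in grid[name if name != "patience" else "patience"]:
                raise ValueError(f"{name}={getattr(self, name)} outside the grid {grid[name]}")


@dataclass
class SDGNNModel:
    """Trained weights bundled with the scalers needed for ppm predictions."""

    params: Params
    config: SDGNNConfig
    scaler: ScalerParams
    target_mean: float
    target_std: float

    def predict(self, graphs: list[MolGraph], scaled: bool = False) -> np.ndarray:
        """Predicted shifts in ppm for raw (or pre-scaled) graphs."""
        if not scaled:
            graphs = [apply_scaler(g, self.scaler) for g in graphs]
        z = forward(self.params, make_batch(graphs))
        return z * self.target_std + self.target_mean

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.params)

    def save(self, path: str | Path) -> None:
        blob = {
            "config": self.config.__dict__,
            "params": {k: v.tolist() for k, v in self.params.items()},
            "scaler": {k: getattr(self.scaler, k).tolist() for k in self.scaler.__dataclass_fields__},
            "target_mean": self.target_mean,
            "target_std": self.target_std,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "SDGNNModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            params={k: np.asarray(v) for k, v in blob["params"].items()},
            config=SDGNNConfig(**blob["config"]),
            scaler=ScalerParams(**{k: np.asarray(v) for k, v in blob["scaler"].items()}),
            target_mean=blob["target_mean"],
            target_std=blob["target_std"],
        )


def _fit(
    train_graphs: list[MolGraph],
    val_graphs: list[MolGraph],
    tcfg: TrainConfig,
    mcfg: SDGNNConfig,
) -> tuple[SDGNNModel, dict]:
    """Mini-batch MAE optimization with early stopping and best-epoch restore."""
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation partitions must be non-empty")
    scaler = fit_scaler(train_graphs)
    tr = [apply_scaler(g, scaler) for g in train_graphs]
    va = [apply_scaler(g, scaler) for g in val_graphs]
    y_tr = np.array([g.y for g in tr])
    t_mean = float(y_tr.mean())
    t_std = float(y_tr.std()) or 1.0
    t_scaled = (y_tr - t_mean) / t_std

    params = init_model(mcfg)
    opt = AdamW(params, lr=tcfg.lr, weight_decay=tcfg.wd)
    rng = np.random.default_rng(tcfg.seed)
    val_batch = make_batch(va)
    y_val = np.array([g.y for g in va])

    best_val = math.inf
    best_params = copy.deepcopy(params)
    best_epoch = 0
    since_best = 0
    history: dict = {"train_loss": [], "val_mae": []}

    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(len(tr))
        epoch_losses = []
        for start in range(0, len(order), tcfg.bs):
            idx = order[start : start + tcfg.bs]
            batch = make_batch([tr[i] for i in idx])
            z, cache = forward(params, batch, return_cache=True)
            resid = z - t_scaled[idx]
            loss = float(np.mean(np.abs(resid)))
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss); "
                    f"lr={tcfg.lr}, hd={mcfg.hidden_dim}"
                )
            grads = backward(params, batch, cache, np.sign(resid) / resid.size)
            opt.step(params, grads)
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))

        z_val = forward(params, val_batch)
        val_mae = mae(y_val, z_val * t_std + t_mean)
        history["val_mae"].append(val_mae)
        if val_mae < best_val:
            best_val, best_epoch, since_best = val_mae, epoch, 0
            best_params = copy.deepcopy(params)
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                break

    history["best_epoch"] = best_epoch
    history["best_val_mae"] = best_val
    model = SDGNNModel(best_params, mcfg, scaler, t_mean, t_std)
    return model, history


def train_model(
    graphs: list[MolGraph], split: SplitPlan, tcfg: TrainConfig, mcfg: SDGNNConfig
) -> tuple[SDGNNModel, dict]:
    """Train on the plan's train partition, early-stop on its validation partition."""
    by_part: dict[str, list[MolGraph]] = {"train": [], "val": [], "test": []}
    for g in graphs:
        part = split.assignment.get(g.record_id)
        if part in by_part:
            by_part[part].append(g)
    return _fit(by_part["train"], by_part["val"], tcfg, mcfg)


# --- grid search ----------------------------------------------------------------

def grid_search(
    grids: dict,
    graphs: list[MolGraph],
    n_cv_folds: int = 3,
    epochs: int = 500,
    seed: int = 0,
    train_fn=None,
) -> tuple[TrainConfig, SDGNNConfig, list[dict]]:
    """Exhaustive grid search scored by k-fold cross-validated validation MAE.

    Every (lr, wd, bs, hd, patience) combination is evaluated by
    ``n_cv_folds``-fold CV on the supplied graphs; the combination with the
    lowest mean validation MAE wins. Ties break toward smaller hd, larger bs,
    lower lr (cheaper models), then lower wd and patience. ``train_fn`` may be
    injected for testing; it maps (train_graphs, val_graphs, tcfg, mcfg) to a
    validation MAE.
    """
    if train_fn is None:
        def train_fn(tr, va, tcfg, mcfg):
            _, hist = _fit(tr, va, tcfg, mcfg)
            return hist["best_val_mae"]

    combos = list(itertools.product(grids["lr"], grids["wd"], grids["bs"], grids["hd"], grids["patience"]))
    kf = KFold(n_splits=n_cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(graphs))
    results = []
    for lr, wd, bs, hd, pat in combos:
        tcfg = TrainConfig(lr=lr, wd=wd, bs=bs, patience=pat, epochs=epochs, seed=seed)
        mcfg = SDGNNConfig(hidden_dim=hd, seed=seed)
        fold_losses = [
            train_fn([graphs[i] for i in tr_idx], [graphs[i] for i in va_idx], tcfg, mcfg)
            for tr_idx, va_idx in folds
        ]
        results.append(
            {"lr": lr, "wd": wd, "bs": bs, "hd": hd, "patience": pat,
             "val_mae": float(np.mean(fold_losses))}
        )
    best = min(results, key=lambda r: (r["val_mae"], r["hd"], -r["bs"], r["lr"], r["wd"], r["patience"]))
    logger.info("grid search over %d combinations; best %s", len(combos), best)
    return (
        TrainConfig(lr=best["lr"], wd=best["wd"], bs=best["bs"], patience=best["patience"],
                    epochs=epochs, seed=seed),
        SDGNNConfig(hidden_dim=best["hd"], seed=seed),
        results,
    )


# --- fold aggregation -----------------------------------------------------------

@dataclass
class MetricsReport:
    fold_mae: list[float]
    fold_rmse: list[float]
    n_per_fold: list[int]
    quantiles: list[dict] = field(default_factory=list)

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))

    @property
    def std_mae(self) -> float:
        return float(np.std(self.fold_mae))  # population std; 1 fold -> 0

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def std_rmse(self) -> float:
        return float(np.std(self.fold_rmse))

    def summary(self) -> str:
        return (
            f"MAE {self.mean_mae:.2f} ± {self.std_mae:.2f} ppm, "
            f"RMSE {self.mean_rmse:.2f} ± {self.std_rmse:.2f} ppm "
            f"({len(self.fold_mae)} folds)"
        )


def evaluate(folds: list[tuple[SDGNNModel, list[MolGraph]]]) -> MetricsReport:
    """Per-fold MAE/RMSE on held-out graphs, aggregated across folds."""
    if not folds:
        raise ValueError("need at least one fold")
    report = MetricsReport([], [], [])
    for model, test_graphs in folds:
        y = np.array([g.y for g in test_graphs])
        yhat = model.predict(test_graphs)
        err = np.abs(y - yhat)
        report.fold_mae.append(mae(y, yhat))
        report.fold_rmse.append(rmse(y, yhat))
        report.n_per_fold.append(len(test_graphs))
        report.quantiles.append(
            {"q50": float(np.percentile(err, 50)), "q95": float(np.percentile(err, 95))}
        )
    return report
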