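"""Optimization loop, hyperparameter random search, Y-randomization.

Training uses Adam with L2 weight decay, minibatches over the training
split, and early stopping on the global validation R2: the returned
parameters are the snapshot from the best-monitored epoch, never a
later one.  All randomness (initialization, shuffling, dropout,
label permutation) flows from explicit integer seeds, and execution is
single-threaded NumPy, so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .curation import CompoundRecord, build_task_table
from .evaluation import per_target_metrics
from .graphs import FeatureSchema, batch_graphs, mol_to_graph
from .network import (MTModelConfig, MTModelState, forward_multitask,
                      init_model, masked_mse_loss)

__all__ = ["TrainConfig", "SearchSpace", "GraphDataset", "Adam", "train",
           "random_search", "y_randomize", "evaluate_split"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    batch_size: int = 256
    max_epochs: int = 1000
    patience: int = 20
    monitor: str = "val_r2"
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0 or self.weight_decay < 0:
            raise ValueError("training hyperparameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass(frozen=True)
class SearchSpace:
    """Random-search grids (the classic lr/dropout/batch sweep)."""

    learning_rates: tuple = (0.1, 0.01, 0.001, 0.0001)
    dropouts: tuple = (0.2, 0.3, 0.4, 0.5)
    batch_sizes: tuple = (64, 128, 256)
    n_trials: int = 8
    trial_epochs: int = 30   # reduced budget per trial; final fit uses full
    seed: int = 0

    def __post_init__(self):
        if not (self.learning_rates and self.dropouts and self.batch_sizes):
            raise ValueError("search grids must be non-empty")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")


class GraphDataset:
    """Featurized molecules + label/mask matrices + split assignment."""

    def __init__(self, records: list[CompoundRecord], targets: list[str],
                 schema: FeatureSchema | None = None):
        self.schema = schema or FeatureSchema()
        self.targets = list(targets)
        self.smiles = [r.canonical_smiles for r in records]
        self.graphs = [mol_to_graph(s, self.schema) for s in self.smiles]
        self.labels, self.mask = build_task_table(records, self.targets)
        self.split = np.array([r.split for r in records])

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == split)

    def restrict_targets(self, targets: list[str]) -> "GraphDataset":
        """A view of the same molecules with a subset of target columns
        (used for single-task comparisons on identical data)."""
        cols = [self.targets.index(t) for t in targets]
        out = object.__new__(GraphDataset)
        out.schema = self.schema
        out.targets = list(targets)
        out.smiles = self.smiles
        out.graphs = self.graphs
        out.labels = self.labels[:, cols]
        out.mask = self.mask[:, cols]
        out.split = self.split
        return out


class Adam:
    """Adam with additive L2 weight decay on the gradient."""

    def __init__(self, params: list, lr: float = 1e-3,
                 weight_decay: float = 0.0, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def evaluate_split(dataset: GraphDataset, state: MTModelState,
                   split: str):
    """Masked per-target + global metrics of a model on one split."""
    idx = dataset.indices(split)
    if len(idx) == 0:
        raise ValueError(f"split {split!r} is empty")
    batch = batch_graphs([dataset.graphs[i] for i in idx])
    raw = forward_multitask(batch, state, train=False).predictions.data
    return per_target_metrics(dataset.labels[idx], dataset.mask[idx],
                              state.rescale(raw), dataset.targets, split=split)


def _global_val_r2(dataset, state) -> float:
    try:
        return evaluate_split(dataset, state, "valid").global_metrics["r2"]
    except ValueError:
        return float("-inf")


def train(dataset: GraphDataset, model_config: MTModelConfig,
          train_config: TrainConfig = TrainConfig(),
          labels: np.ndarray | None = None, mask: np.ndarray | None = None,
          ) -> tuple[MTModelState, pd.DataFrame]:
    """Fit the multitask network; return best-epoch state and history.

    ``labels``/``mask`` may override the dataset's matrices (used by
    Y-randomization to train on permuted labels without touching the
    original data).
    """
    labels = dataset.labels if labels is None else labels
    mask = dataset.mask if mask is None else mask
    train_idx = dataset.indices("train")
    if len(train_idx) == 0:
        raise ValueError("training split is empty")
    if not mask[train_idx].any():
        raise ValueError("no labelled training entries")

    state = init_model(model_config, dataset.schema)
    # per-target label standardization fitted on the training split
    T = labels.shape[1]
    y_mean, y_std = np.zeros(T), np.ones(T)
    for j in range(T):
        vals = labels[train_idx, j][mask[train_idx, j]]
        if len(vals):
            y_mean[j] = vals.mean()
            y_std[j] = vals.std() if vals.std() > 0 else 1.0
    state.y_mean, state.y_std = y_mean, y_std
    scaled_labels = np.where(mask, (labels - y_mean) / y_std, 0.0)

    opt = Adam(state.trainables(), lr=train_config.learning_rate,
               weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)

    # swap matrices in for validation scoring as well
    orig = (dataset.labels, dataset.mask)
    dataset.labels, dataset.mask = labels, mask
    history = []
    best_metric, best_epoch, best_params = -np.inf, -1, state.copy_params()
    try:
        for epoch in range(train_config.max_epochs):
            perm = rng.permutation(train_idx)
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, len(perm), train_config.batch_size):
                sub = perm[lo:lo + train_config.batch_size]
                if not mask[sub].any():
                    continue
                batch = batch_graphs([dataset.graphs[i] for i in sub])
                res = forward_multitask(batch, state, train=True,
                                        dropout_rng=rng)
                loss = masked_mse_loss(res.predictions, scaled_labels[sub],
                                       mask[sub])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"loss diverged (non-finite) at epoch {epoch}")
                state.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            val_r2 = _global_val_r2(dataset, state)
            history.append({"epoch": epoch,
                            "train_loss": epoch_loss / max(n_batches, 1),
                            "val_r2": val_r2})
            if val_r2 > best_metric:
                best_metric, best_epoch = val_r2, epoch
                best_params = state.copy_params()
            elif epoch - best_epoch >= train_config.patience:
                break
    finally:
        dataset.labels, dataset.mask = orig
    state.load_params(best_params)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    hist.attrs["best_val_r2"] = best_metric
    return state, hist


def random_search(dataset: GraphDataset, model_config: MTModelConfig,
                  space: SearchSpace = SearchSpace()
                  ) -> tuple[pd.DataFrame, MTModelConfig, TrainConfig]:
    """Random hyperparameter search ranked by validation R2.

    Each trial is a full (reduced-budget) training run; the emitted
    table lists every trial's configuration and score.
    """
    rng = np.random.default_rng(space.seed)
    rows = []
    for trial in range(space.n_trials):
        lr = float(space.learning_rates[rng.integers(len(space.learning_rates))])
        dropout = float(space.dropouts[rng.integers(len(space.dropouts))])
        bs = int(space.batch_sizes[rng.integers(len(space.batch_sizes))])
        mc = replace(model_config, dropout=dropout)
        tc = TrainConfig(learning_rate=lr, batch_size=bs,
                         max_epochs=space.trial_epochs,
                         patience=space.trial_epochs - 1, seed=space.seed)
        _, hist = train(dataset, mc, tc)
        rows.append({"trial": trial, "learning_rate": lr, "dropout": dropout,
                     "batch_size": bs,
                     "val_r2": hist.attrs["best_val_r2"]})
    table = pd.DataFrame(rows).sort_values("val_r2", ascending=False,
                                           kind="stable").reset_index(drop=True)
    best = table.iloc[0]
    best_mc = replace(model_config, dropout=float(best["dropout"]))
    best_tc = TrainConfig(learning_rate=float(best["learning_rate"]),
                          batch_size=int(best["batch_size"]))
    return table, best_mc, best_tc


def shuffle_labels(labels: np.ndarray, mask: np.ndarray, idx: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Permute labels within each target column over labelled rows of idx.

    The mask pattern stays fixed, so per-task sample sizes and the label
    multiset per target are conserved.
    """
    shuffled = labels.copy()
    for j in range(labels.shape[1]):
        rows = idx[mask[idx, j]]
        shuffled[rows, j] = labels[rng.permutation(rows), j]
    return shuffled


def y_randomize(dataset: GraphDataset, model_config: MTModelConfig,
                train_config: TrainConfig = TrainConfig(),
                n_rounds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Label-shuffling robustness check.

    Per round, pIC50 labels of the train and validation splits are
    permuted within each target column (different seed per round), the
    model is retrained from scratch, and train/validation R2 are
    recorded.  A robust model shows a large drop versus the unshuffled
    fit; the original dataset is left untouched.
    """
    if n_rounds < 1:
        raise ValueError("need at least one round")
    idx = np.concatenate([dataset.indices("train"), dataset.indices("valid")])
    rows = []
    for rnd in range(n_rounds):
        rng = np.random.default_rng(seed + 1000 * rnd + 17)
        shuffled = shuffle_labels(dataset.labels, dataset.mask, idx, rng)
        state, hist = train(dataset, model_config, train_config,
                            labels=shuffled, mask=dataset.mask)
        orig = (dataset.labels, dataset.mask)
        dataset.labels = shuffled
        try:
            train_rep = evaluate_split(dataset, state, "train")
            valid_rep = evaluate_split(dataset, state, "valid")
        finally:
            dataset.labels, dataset.mask = orig
        rows.append({"round": rnd,
                     "train_r2": train_rep.global_metrics["r2"],
                     "valid_r2": valid_rep.global_metrics["r2"]})
    return pd.DataFrame(rows)
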