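"""Train the multitask graph-attention regressor on a synthetic panel.

Generates a 200-molecule library with planted pharmacophore effects on
four correlated kinase-like targets, trains a compact network, and
prints per-target and global test metrics plus the 1 uM threshold AUC.
Runs in about a minute on one CPU.
"""

import numpy as np

from mtqsar.evaluation import auc_at_threshold
from mtqsar.graphs import batch_graphs
from mtqsar.network import MTModelConfig, forward_multitask
from mtqsar.synthetic import FixtureSpec, make_fixture_dataset
from mtqsar.training import GraphDataset, TrainConfig, evaluate_split, train

spec = FixtureSpec(n_molecules=200, seed=7)
records, _ = make_fixture_dataset(spec)
dataset = GraphDataset(records, list(spec.targets))

model_cfg = MTModelConfig(targets=spec.targets, graph_feat_size=40,
                          dropout=0.1, seed=7)
train_cfg = TrainConfig(learning_rate=3e-3, batch_size=64, max_epochs=60,
                        patience=59, seed=7)
state, history = train(dataset, model_cfg, train_cfg)
print(f"best epoch {history.attrs['best_epoch']}, "
      f"validation R2 {history.attrs['best_val_r2']:.3f}\n")

report = evaluate_split(dataset, state, "test")
print(report)

idx = dataset.indices("test")
preds = state.rescale(forward_multitask(
    batch_graphs([dataset.graphs[i] for i in idx]), state).predictions.data)
sel = dataset.mask[idx, 0]
auc = auc_at_threshold(dataset.labels[idx][sel, 0], preds[sel, 0])
print(f"\n{dataset.targets[0]} active/inactive AUC at 1 uM: {auc:.3f}")

# R2 close to the noise ceiling (label noise sd 0.3 on ~1 pIC50 unit of
# signal) and AUC near 1 indicate the network has learned the planted
# structure-activity relationships, not memorized labels.
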