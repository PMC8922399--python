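"""Canned desk-scale validation experiments on synthetic fixtures.

Each function builds its own fixture dataset, runs the relevant part of
the workflow, and returns plain dictionaries of measured quantities.
They encode the package's standard study conditions: libraries of a few
hundred kinase-inhibitor-like molecules, four correlated targets with
sparse labels, and compact network/training settings chosen so a full
experiment finishes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .graphs import batch_graphs
from .network import MTModelConfig, forward_multitask, init_model
from .synthetic import FixtureSpec, make_fixture_dataset
from .training import GraphDataset, TrainConfig, evaluate_split, train, y_randomize

__all__ = ["desk_model_config", "desk_train_config",
           "attention_normalization_check", "multitask_vs_single_task",
           "y_randomization_gap", "attribution_recovery",
           "single_task_reduction_check"]

# compact desk-scale settings: 40-unit trunk, minibatch Adam
_DESK_FEAT_SIZE = 40
_DESK_EPOCHS = 60
_DESK_LR = 3e-3
_DESK_BATCH = 64


def desk_model_config(targets, seed: int, dropout: float = 0.1
                      ) -> MTModelConfig:
    return MTModelConfig(targets=tuple(targets),
                         graph_feat_size=_DESK_FEAT_SIZE,
                         dropout=dropout, seed=seed)


def desk_train_config(seed: int, epochs: int = _DESK_EPOCHS) -> TrainConfig:
    return TrainConfig(learning_rate=_DESK_LR, batch_size=_DESK_BATCH,
                       max_epochs=epochs, patience=epochs - 1, seed=seed)


def attention_normalization_check(n_molecules: int = 100,
                                  seed: int = 0) -> dict:
    """Max deviation of per-node attention sums from 1, over all layers
    of an untrained model on a random fixture library."""
    spec = FixtureSpec(n_molecules=n_molecules, seed=seed)
    records, _ = make_fixture_dataset(spec)
    ds = GraphDataset(records, list(spec.targets))
    state = init_model(desk_model_config(spec.targets, seed), ds.schema)
    batch = batch_graphs(ds.graphs)
    res = forward_multitask(batch, state, train=False)
    worst = 0.0
    for alpha in res.attention_per_layer:
        sums = np.zeros(batch.n_atoms)
        np.add.at(sums, res.edge_dst, alpha)
        worst = max(worst, float(np.abs(sums - 1.0).max()))
    for alpha in res.readout_attention:
        sums = np.zeros(batch.n_mols)
        np.add.at(sums, batch.mol_index, alpha)
        worst = max(worst, float(np.abs(sums - 1.0).max()))
    return {"max_deviation": worst, "n_molecules": n_molecules}


def multitask_vs_single_task(n_molecules: int = 400,
                             seeds: tuple = (0, 1, 2),
                             sparse_target_index: int = 3) -> dict:
    """Small-target benefit of joint training.

    One target is thinned to 10% label density; the multitask network
    (all four heads) and a single-task network trained only on the
    sparse target get an identical budget, data split and evaluation.
    Returns per-seed and median test R2 on the sparse target.
    """
    missingness = [0.3, 0.2, 0.5, 0.9]
    missingness[sparse_target_index] = 0.9
    mt_scores, st_scores = [], []
    for seed in seeds:
        spec = FixtureSpec(n_molecules=n_molecules,
                           label_missingness=tuple(missingness), seed=seed)
        records, _ = make_fixture_dataset(spec)
        targets = list(spec.targets)
        sparse = targets[sparse_target_index]
        ds = GraphDataset(records, targets)
        tc = desk_train_config(seed)

        mt_state, _ = train(ds, desk_model_config(targets, seed), tc)
        mt_rep = evaluate_split(ds, mt_state, "test")
        mt_scores.append(mt_rep.per_target[sparse].get("r2", float("nan")))

        ds_single = ds.restrict_targets([sparse])
        st_state, _ = train(ds_single, desk_model_config([sparse], seed), tc)
        st_rep = evaluate_split(ds_single, st_state, "test")
        st_scores.append(st_rep.per_target[sparse].get("r2", float("nan")))
    return {"target": sparse, "seeds": list(seeds),
            "multitask_r2": mt_scores, "singletask_r2": st_scores,
            "multitask_median": float(np.median(mt_scores)),
            "singletask_median": float(np.median(st_scores))}


def y_randomization_gap(n_molecules: int = 240, n_rounds: int = 3,
                        seed: int = 0) -> dict:
    """Validation R2 of the real fit versus label-shuffled refits."""
    spec = FixtureSpec(n_molecules=n_molecules, seed=seed)
    records, _ = make_fixture_dataset(spec)
    ds = GraphDataset(records, list(spec.targets))
    mc = desk_model_config(spec.targets, seed)
    tc = desk_train_config(seed)
    state, hist = train(ds, mc, tc)
    base_val = evaluate_split(ds, state, "valid").global_metrics["r2"]
    table = y_randomize(ds, mc, tc, n_rounds=n_rounds, seed=seed)
    shuffled = table["valid_r2"].tolist()
    return {"unshuffled_valid_r2": float(base_val),
            "shuffled_valid_r2": shuffled,
            "min_gap": float(base_val - max(shuffled))}


def attribution_recovery(seeds: tuple = (0, 1, 2, 3, 4),
                         n_molecules: int = 240,
                         smarts: str = "S(=O)(=O)N") -> dict:
    """Planted-substructure recovery by attention attribution.

    The fixture plants a +2.0 pIC50 effect on the sulfonamide group.
    For each seed, a model is trained and atom weights of all test
    molecules carrying the group are pooled into region (matched atoms)
    versus complement; a one-sided rank-sum test asks whether region
    weights are stochastically greater.
    """
    from .interpretation import atom_weights, normalize_weights
    from .interpretation import rank_sum_region_test

    p_values = []
    for seed in seeds:
        spec = FixtureSpec(n_molecules=n_molecules, seed=seed)
        records, data = make_fixture_dataset(spec)
        ds = GraphDataset(records, list(spec.targets))
        state, _ = train(ds, desk_model_config(spec.targets, seed),
                         desk_train_config(seed))
        pooled, region = [], []
        offset = 0
        for i, rec in enumerate(records):
            if rec.split != "test" or smarts not in data.matched_atoms[i]:
                continue
            w = normalize_weights(
                atom_weights(rec.canonical_smiles, state, schema=ds.schema))
            pooled.extend(w.tolist())
            region.extend(offset + a for a in data.matched_atoms[i][smarts])
            offset += len(w)
        test = rank_sum_region_test(np.array(pooled), region)
        p_values.append(test.p_value)
    n_sig = int(sum(p < 0.05 for p in p_values))
    return {"smarts": smarts, "p_values": p_values,
            "n_significant": n_sig, "n_seeds": len(seeds)}


def fixture_benchmark(n_molecules: int = 300, seed: int = 0) -> dict:
    """Train one multitask model on a fixture library and report test
    metrics, the 1 uM threshold AUC, and a LightGBM fingerprint
    baseline on the identical split."""
    from .evaluation import auc_at_threshold, gbm_baseline, pooled_metrics

    spec = FixtureSpec(n_molecules=n_molecules, seed=seed)
    records, _ = make_fixture_dataset(spec)
    ds = GraphDataset(records, list(spec.targets))
    state, hist = train(ds, desk_model_config(spec.targets, seed),
                        desk_train_config(seed))
    report = evaluate_split(ds, state, "test")

    idx = ds.indices("test")
    batch = batch_graphs([ds.graphs[i] for i in idx])
    preds = state.rescale(
        forward_multitask(batch, state, train=False).predictions.data)
    aucs = []
    for j in range(len(ds.targets)):
        sel = ds.mask[idx, j]
        y = ds.labels[idx][sel, j]
        if sel.sum() >= 2 and (y >= 6).any() and (y < 6).any():
            aucs.append(auc_at_threshold(y, preds[sel, j]))
    gbm = gbm_baseline([r.canonical_smiles for r in records], ds.labels,
                       ds.mask, ds.split, ds.targets, seed=seed,
                       n_estimators=100)
    return {"test_global": report.global_metrics,
            "test_pooled": pooled_metrics(ds.labels[idx], ds.mask[idx], preds),
            "auc_mean": float(np.mean(aucs)) if aucs else float("nan"),
            "gbm_test_global_r2": gbm.global_metrics["r2"],
            "best_epoch": int(hist.attrs["best_epoch"]),
            "n_molecules": n_molecules}


def single_task_reduction_check(seed: int = 0, n_molecules: int = 30) -> dict:
    """Bitwise agreement of a one-target multitask forward pass with the
    single-task forward under a shared seed."""
    from .network import single_task_config

    spec = FixtureSpec(n_molecules=n_molecules, seed=seed)
    records, _ = make_fixture_dataset(spec)
    ds = GraphDataset(records, list(spec.targets))
    batch = batch_graphs(ds.graphs)
    mt_cfg = desk_model_config([spec.targets[0]], seed)
    st_cfg = single_task_config(
        desk_model_config(spec.targets, seed), spec.targets[0])
    mt_pred = forward_multitask(batch, init_model(mt_cfg, ds.schema)).predictions.data
    st_pred = forward_multitask(batch, init_model(st_cfg, ds.schema)).predictions.data
    return {"max_abs_diff": float(np.abs(mt_pred - st_pred).max()),
            "bitwise_equal": bool(np.array_equal(mt_pred, st_pred))}
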