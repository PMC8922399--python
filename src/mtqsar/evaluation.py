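"""Regression metrics, threshold AUC and a gradient-boosted baseline.

Per-target R2 / MAE / RMSE are computed over labelled entries only and
averaged (unweighted) across targets into global metrics.  For external
comparisons, continuous pIC50 predictions are scored as a ranking of
active (IC50 <= 1 uM, i.e. pIC50 >= 6) versus inactive compounds with a
rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "r2", "mae", "rmse", "per_target_metrics",
           "global_metrics", "pooled_metrics", "auc_at_threshold",
           "gbm_baseline", "morgan_fingerprints"]


@dataclass
class MetricsReport:
    split: str = ""
    per_target: dict = field(default_factory=dict)  # target -> metric dict
    global_metrics: dict = field(default_factory=dict)

    def __str__(self):
        lines = [f"[{self.split}] global: " + "  ".join(
            f"{k}={v:.3f}" for k, v in self.global_metrics.items())]
        for t, m in self.per_target.items():
            lines.append(f"  {t}: " + "  ".join(
                f"{k}={v:.3f}" if k != "n" else f"n={v}"
                for k, v in m.items()))
        return "\n".join(lines)


def _paired(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError("y and yhat must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    return y, yhat


def r2(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y, yhat = _paired(y, yhat)
    if len(y) < 2:
        raise ValueError("R2 needs at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined for zero-variance observations")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot


def mae(y, yhat) -> float:
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    y, yhat = _paired(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def per_target_metrics(labels: np.ndarray, mask: np.ndarray,
                       preds: np.ndarray, targets: list[str],
                       split: str = "") -> MetricsReport:
    """Masked per-target metrics; targets with <2 labels or zero label
    variance are reported with n only."""
    report = MetricsReport(split=split)
    for j, t in enumerate(targets):
        sel = mask[:, j]
        m = {"n": int(sel.sum())}
        if m["n"] >= 2 and np.ptp(labels[sel, j]) > 0:
            m["r2"] = r2(labels[sel, j], preds[sel, j])
            m["mae"] = mae(labels[sel, j], preds[sel, j])
            m["rmse"] = rmse(labels[sel, j], preds[sel, j])
        report.per_target[t] = m
    report.global_metrics = global_metrics(report.per_target)
    return report


def global_metrics(per_target: dict) -> dict:
    """Unweighted mean of per-target metrics across valid targets."""
    valid = [m for m in per_target.values() if "r2" in m]
    if not valid:
        raise ValueError("no target has computable metrics")
    return {k: float(np.mean([m[k] for m in valid]))
            for k in ("r2", "mae", "rmse")}


def pooled_metrics(labels: np.ndarray, mask: np.ndarray,
                   preds: np.ndarray) -> dict:
    """Alternative aggregation: pool all labelled entries across targets."""
    y, yhat = labels[mask], preds[mask]
    return {"r2": r2(y, yhat), "mae": mae(y, yhat), "rmse": rmse(y, yhat)}


def auc_at_threshold(y_pic50, yhat_pic50, threshold_pic50: float = 6.0) -> float:
    """Rank-based AUC of continuous predictions against binarized truth.

    Truth is active iff pIC50 >= threshold (IC50 at or below 1 uM by
    default); ties in predictions receive midranks, so constant
    predictions score 0.5.
    """
    from scipy.stats import rankdata
    y, yhat = _paired(y_pic50, yhat_pic50)
    pos = y >= threshold_pic50
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both active and inactive compounds")
    ranks = rankdata(yhat)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# -- gradient-boosted baseline -----------------------------------------

def morgan_fingerprints(smiles_list: list[str], n_bits: int = 1024,
                        radius: int = 2) -> np.ndarray:
    """Circular (ECFP-style) fingerprint bit matrix, shape (n, n_bits)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    out = np.zeros((len(smiles_list), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"cannot parse {smi!r}")
        fp = gen.GetFingerprint(mol)
        out[i, list(fp.GetOnBits())] = 1
    return out


def gbm_baseline(smiles: list[str], labels: np.ndarray, mask: np.ndarray,
                 split: np.ndarray, targets: list[str],
                 fingerprint_bits: int = 1024, seed: int = 0,
                 n_estimators: int = 200) -> MetricsReport:
    """One LightGBM regressor per target on circular fingerprints.

    Trains on the ``train`` split and reports test-split metrics on the
    identical partition used by the graph model.  Targets with fewer
    than 10 training labels are skipped with a warning entry.
    """
    import lightgbm as lgb
    X = morgan_fingerprints(smiles, n_bits=fingerprint_bits).astype(np.float64)
    split = np.asarray(split)
    is_train, is_test = split == "train", split == "test"
    report = MetricsReport(split="test")
    for j, t in enumerate(targets):
        tr = is_train & mask[:, j]
        te = is_test & mask[:, j]
        if tr.sum() < 10:
            report.per_target[t] = {"n": int(te.sum()), "skipped": True}
            continue
        model = lgb.LGBMRegressor(n_estimators=n_estimators, random_state=seed,
                                  n_jobs=1, verbose=-1)
        model.fit(X[tr], labels[tr, j])
        import warnings
        with warnings.catch_warnings():
            # LightGBM's sklearn wrapper warns about absent feature names
            # even though fit and predict both receive plain arrays
            warnings.simplefilter("ignore", UserWarning)
            pred = model.predict(X[te])
        m = {"n": int(te.sum())}
        if m["n"] >= 2 and np.ptp(labels[te, j]) > 0:
            m["r2"] = r2(labels[te, j], pred)
            m["mae"] = mae(labels[te, j], pred)
            m["rmse"] = rmse(labels[te, j], pred)
        report.per_target[t] = m
    report.global_metrics = global_metrics(report.per_target)
    return report
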