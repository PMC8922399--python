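"""Distance-to-model applicability domain on Morgan fingerprints.

The domain threshold is

    D_T = d_ave + Z * theta

where ``d_ave`` is the mean distance from each training compound to its
nearest *other* training compound, ``theta`` the corresponding standard
deviation, and ``Z`` a significance parameter (negative Z tightens the
domain).  A query compound is inside the domain iff none of its k
nearest training distances exceeds D_T.

Two distance kernels are provided on binary fingerprints: ``one_minus_
tanimoto`` (default) and ``euclidean_normalized`` (Euclidean divided by
sqrt(n_bits)); both live in [0, 1] so thresholds are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd

from .evaluation import morgan_fingerprints, per_target_metrics

__all__ = ["ADModel", "ADVerdict", "domain_threshold", "fit_ad", "classify",
           "classify_fingerprint", "sweep", "save_ad", "load_ad",
           "pairwise_distances"]

_KINDS = ("one_minus_tanimoto", "euclidean_normalized")


@dataclass
class ADModel:
    training_fingerprints: np.ndarray   # (n, n_bits) uint8
    d_ave: float
    theta: float
    Z: float
    k: int
    D_T: float
    distance_kind: str = "one_minus_tanimoto"
    n_bits: int = 2048
    radius: int = 2


@dataclass
class ADVerdict:
    distances: np.ndarray               # k nearest, ascending
    in_domain: bool


def domain_threshold(d_ave: float, theta: float, Z: float) -> float:
    """D_T = d_ave + Z * theta (linear in Z with slope theta)."""
    return d_ave + Z * theta


def pairwise_distances(A: np.ndarray, B: np.ndarray,
                       kind: str = "one_minus_tanimoto") -> np.ndarray:
    """Dense distance matrix between two binary fingerprint sets."""
    if kind not in _KINDS:
        raise ValueError(f"unknown distance kind {kind!r}")
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    inner = A @ B.T
    ca = A.sum(axis=1)[:, None]
    cb = B.sum(axis=1)[None, :]
    if kind == "one_minus_tanimoto":
        union = ca + cb - inner
        with np.errstate(invalid="ignore"):
            sim = np.where(union > 0, inner / np.maximum(union, 1e-300), 1.0)
        return 1.0 - sim
    sq = np.maximum(ca + cb - 2.0 * inner, 0.0)
    return np.sqrt(sq) / np.sqrt(A.shape[1])


def fit_ad(train_smiles: list[str], distance_kind: str = "one_minus_tanimoto",
           Z: float = -0.25, k: int = 3, n_bits: int = 2048,
           radius: int = 2) -> ADModel:
    """Fit d_ave and theta from nearest-other-neighbor training distances."""
    if len(train_smiles) < 2:
        raise ValueError("need at least two training molecules")
    fps = morgan_fingerprints(train_smiles, n_bits=n_bits, radius=radius)
    dist = pairwise_distances(fps, fps, kind=distance_kind)
    np.fill_diagonal(dist, np.inf)          # self-exclusion
    nearest = dist.min(axis=1)
    d_ave = float(nearest.mean())
    theta = float(nearest.std())
    return ADModel(training_fingerprints=fps, d_ave=d_ave, theta=theta,
                   Z=Z, k=k, D_T=domain_threshold(d_ave, theta, Z),
                   distance_kind=distance_kind, n_bits=n_bits, radius=radius)


def _query_distances(smiles_list: list[str], ad: ADModel) -> np.ndarray:
    fps = morgan_fingerprints(smiles_list, n_bits=ad.n_bits, radius=ad.radius)
    return pairwise_distances(fps, ad.training_fingerprints,
                              kind=ad.distance_kind)


def classify_fingerprint(fp: np.ndarray, ad: ADModel) -> ADVerdict:
    """k-NN domain verdict from a precomputed binary fingerprint."""
    if ad.k > len(ad.training_fingerprints):
        raise ValueError("k exceeds the training-set size")
    if ad.k < 1:
        raise ValueError("k must be at least 1")
    dist = pairwise_distances(np.atleast_2d(fp), ad.training_fingerprints,
                              kind=ad.distance_kind)[0]
    d = np.sort(dist)[:ad.k]
    return ADVerdict(distances=d, in_domain=bool(d.max() <= ad.D_T))


def classify(smiles: str, ad: ADModel) -> ADVerdict:
    """k-NN domain verdict: inside iff all k nearest distances <= D_T."""
    fp = morgan_fingerprints([smiles], n_bits=ad.n_bits, radius=ad.radius)[0]
    return classify_fingerprint(fp, ad)


def sweep(test_smiles: list[str], ad: ADModel, k_values: list[int],
          Z_values: list[float], labels: np.ndarray | None = None,
          mask: np.ndarray | None = None, preds: np.ndarray | None = None,
          targets: list[str] | None = None
          ) -> tuple[pd.DataFrame, dict]:
    """Grid over (k, Z): out-of-domain counts and optional ID/OD metrics.

    With ``labels``/``mask``/``preds`` given, per-partition metric
    reports are produced for every grid point (the classic ID-versus-OD
    performance table).
    """
    if not len(k_values) or not len(Z_values):
        raise ValueError("empty sweep grid")
    dist = _query_distances(test_smiles, ad)
    dist_sorted = np.sort(dist, axis=1)
    rows, reports = [], {}
    for k in k_values:
        if k > dist.shape[1]:
            raise ValueError("k exceeds the training-set size")
        kth = dist_sorted[:, :k].max(axis=1)
        for Z in Z_values:
            d_t = domain_threshold(ad.d_ave, ad.theta, Z)
            od = kth > d_t
            rows.append({"k": k, "Z": Z, "D_T": d_t,
                         "n_OD": int(od.sum()), "n_ID": int((~od).sum())})
            if labels is not None and preds is not None:
                part = {}
                for name, sel in (("ID", ~od), ("OD", od)):
                    if sel.sum() >= 2:
                        try:
                            part[name] = per_target_metrics(
                                labels[sel], mask[sel], preds[sel],
                                targets, split=name)
                        except ValueError:
                            pass
                reports[(k, Z)] = part
    return pd.DataFrame(rows), reports


# -- serialization ------------------------------------------------------

def save_ad(ad: ADModel, path: str) -> None:
    payload = asdict(ad)
    payload["training_fingerprints"] = [
        "".join(map(str, row)) for row in ad.training_fingerprints]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ad(path: str) -> ADModel:
    with open(path) as fh:
        payload = json.load(fh)
    payload["training_fingerprints"] = np.array(
        [[int(c) for c in row] for row in payload["training_fingerprints"]],
        dtype=np.uint8)
    return ADModel(**payload)
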