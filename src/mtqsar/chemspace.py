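"""Dataset diagnostics: chemical space, drug-likeness, task relatedness.

* PCA of 167-bit MACCS structural keys (first three components) to
  visualize how train/validation/test occupy chemical space.
* QED drug-likeness distributions per target with pairwise overlap
  areas of their kernel-density curves on [0, 1].
* Inter-task correlation of pIC50 labels on pairwise-complete entries
  (Pearson by default, Spearman optionally) -- the usual justification
  for training the four tasks jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, QED

__all__ = ["ChemspaceReport", "maccs_matrix", "pca_space", "qed_profile",
           "task_correlation"]


@dataclass
class ChemspaceReport:
    pca_coordinates: np.ndarray = None       # (n, 3)
    explained_variance: np.ndarray = None    # (3,) ratios, non-increasing
    split_overlap: dict = field(default_factory=dict)
    qed_values: dict = field(default_factory=dict)       # target -> array
    qed_overlap: dict = field(default_factory=dict)      # (t1,t2) -> area
    task_correlation: np.ndarray = None


def maccs_matrix(smiles_list: list[str]) -> np.ndarray:
    """MACCS key bit matrix, shape (n, 167)."""
    out = np.zeros((len(smiles_list), 167), dtype=np.uint8)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"cannot parse {smi!r}")
        fp = MACCSkeys.GenMACCSKeys(mol)
        out[i, list(fp.GetOnBits())] = 1
    return out


def pca_space(smiles_list: list[str],
              splits: np.ndarray | None = None) -> ChemspaceReport:
    """First three principal components of the pooled MACCS matrix.

    The split-overlap summary reports, for each non-training split, the
    fraction of its points lying within the training split's bounding
    box in PC space (1.0 = fully enclosed).
    """
    from sklearn.decomposition import PCA
    if len(smiles_list) < 4:
        raise ValueError("need at least 4 molecules for a 3-component PCA")
    X = maccs_matrix(smiles_list).astype(float)
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("degenerate input: all MACCS keys identical")
    pca = PCA(n_components=3, svd_solver="full")
    coords = pca.fit_transform(X)
    report = ChemspaceReport(pca_coordinates=coords,
                             explained_variance=pca.explained_variance_ratio_)
    if splits is not None:
        splits = np.asarray(splits)
        train = coords[splits == "train"]
        if len(train):
            lo, hi = train.min(axis=0), train.max(axis=0)
            for name in np.unique(splits):
                if name == "train":
                    continue
                pts = coords[splits == name]
                inside = np.all((pts >= lo) & (pts <= hi), axis=1)
                report.split_overlap[str(name)] = float(inside.mean())
    return report


def _density_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """KDE evaluated on the grid and normalized to integrate to one.

    Degenerate samples (fewer than 2 distinct values) become a narrow
    Gaussian bump so overlap areas stay well defined.
    """
    from scipy.stats import gaussian_kde
    values = np.asarray(values, dtype=float)
    if len(np.unique(values)) < 2:
        center = values[0]
        dens = np.exp(-0.5 * ((grid - center) / 0.01) ** 2)
    else:
        dens = gaussian_kde(values)(grid)
    area = np.trapezoid(dens, grid)
    return dens / area if area > 0 else dens


def qed_profile(per_target_smiles: dict, grid_points: int = 512
                ) -> tuple[dict, dict]:
    """QED values per target and pairwise density-overlap areas.

    Overlap area = integral of min(f, g) over [0, 1] of the two
    normalized density curves; identical molecule sets give 1.0.
    """
    grid = np.linspace(0.0, 1.0, grid_points)
    qed_values, densities = {}, {}
    for target, smiles_list in per_target_smiles.items():
        if not smiles_list:
            continue
        vals = []
        for smi in smiles_list:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"cannot parse {smi!r}")
            vals.append(QED.qed(mol))
        qed_values[target] = np.array(vals)
        densities[target] = _density_on_grid(qed_values[target], grid)
    overlap = {}
    names = list(qed_values)
    for i, t1 in enumerate(names):
        for t2 in names[i + 1:]:
            area = float(np.trapezoid(np.minimum(densities[t1],
                                                 densities[t2]), grid))
            overlap[(t1, t2)] = min(area, 1.0)
    return qed_values, overlap


def task_correlation(labels: np.ndarray, mask: np.ndarray,
                     method: str = "pearson",
                     min_overlap: int = 3) -> np.ndarray:
    """T x T label correlation on pairwise-complete molecules.

    Pairs with fewer than ``min_overlap`` co-labelled molecules are
    flagged as NaN.  The matrix is symmetric with a unit diagonal.
    """
    from scipy.stats import pearsonr, spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    T = labels.shape[1]
    corr = np.full((T, T), np.nan)
    np.fill_diagonal(corr, 1.0)
    for i in range(T):
        for j in range(i + 1, T):
            both = mask[:, i] & mask[:, j]
            if both.sum() < min_overlap:
                continue
            x, y = labels[both, i], labels[both, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if method == "pearson":
                corr[i, j] = corr[j, i] = pearsonr(x, y).statistic
            else:
                corr[i, j] = corr[j, i] = spearmanr(x, y).statistic
    return corr
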