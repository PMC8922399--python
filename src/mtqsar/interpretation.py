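"""Per-atom attribution of predictions, with substructure significance.

Two attribution routes are exposed behind one interface:

``attention``  (default) -- the readout attention the super-node paid to
    each atom, averaged over readout timesteps.  These weights are
    nonnegative and sum to one per molecule, matching the usual
    presentation of attention-based atom maps; they are shared across
    target heads.
``saliency`` -- gradient attribution: the L2 norm, per atom, of the
    gradient of a head's output with respect to that atom's initial
    embedding.  This route is head-specific, so it can be computed per
    target or as the mean across heads.

Weights are min-max normalized per molecule for display; atoms whose
weight exceeds the molecule average are called *key atoms*, and a
one-sided Wilcoxon rank-sum test decides whether a chosen region's
weights are stochastically greater than the rest of the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from rdkit import Chem

from .graphs import FeatureSchema, batch_graphs, mol_to_graph
from .network import MTModelState, forward_multitask
from .tensor import Tensor

__all__ = ["AtomAttribution", "SubstructureTest", "atom_weights",
           "normalize_weights", "attribute", "rank_sum_region_test",
           "region_from_smarts", "render_attribution"]


@dataclass
class AtomAttribution:
    canonical_smiles: str
    raw_weights: np.ndarray
    normalized_weights: np.ndarray
    molecule_mean: float              # mean of normalized weights
    key_atoms: tuple                  # indices with weight above the mean
    method: str = "attention"


@dataclass
class SubstructureTest:
    region: tuple                     # atom indices, set A
    complement: tuple                 # remaining atoms, set B
    region_mean: float
    complement_mean: float
    region_mean_raw: float
    complement_mean_raw: float
    p_value: float
    significant: bool                 # p < 0.05
    statistic: float                  # Mann-Whitney U of A over B


def atom_weights(smiles: str, state: MTModelState,
                 method: str = "attention",
                 target: str | None = None,
                 schema: FeatureSchema | None = None) -> np.ndarray:
    """Raw nonnegative per-atom weights for one molecule.

    ``target=None`` gives the all-task view (attention is inherently
    shared; saliency backpropagates from the sum over heads, i.e. the
    mean contribution across tasks up to scale).
    """
    schema = schema or FeatureSchema()
    if schema.fingerprint() != state.schema_hash:
        raise ValueError("feature schema does not match the trained model")
    batch = batch_graphs([mol_to_graph(smiles, schema)])
    result = forward_multitask(batch, state, train=False)
    if method == "attention":
        return np.mean(result.readout_attention, axis=0)
    if method == "saliency":
        pred = result.predictions
        if target is not None:
            j = state.config.targets.index(target)
            sel = np.zeros(len(state.config.targets))
            sel[j] = 1.0
            score = (pred * Tensor(sel)).sum()
        else:
            score = pred.sum()
        score.backward()
        g = result.atom_embedding.grad
        return np.sqrt((g ** 2).sum(axis=1))
    raise ValueError(f"unknown attribution method {method!r}")


def normalize_weights(raw: np.ndarray) -> np.ndarray:
    """Per-molecule min-max scaling to [0,1]; constant vectors map to 0.5."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("no atoms to normalize")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def attribute(smiles: str, state: MTModelState, method: str = "attention",
              target: str | None = None,
              schema: FeatureSchema | None = None) -> AtomAttribution:
    raw = atom_weights(smiles, state, method=method, target=target,
                       schema=schema)
    norm = normalize_weights(raw)
    mean = float(norm.mean())
    key = tuple(int(i) for i in np.flatnonzero(norm > mean))
    return AtomAttribution(canonical_smiles=smiles, raw_weights=raw,
                           normalized_weights=norm, molecule_mean=mean,
                           key_atoms=key, method=method)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of A over B with half-credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum_region_test(weights: np.ndarray, region: list[int],
                         raw_weights: np.ndarray | None = None,
                         exact_max_n: int = 12) -> SubstructureTest:
    """One-sided rank-sum test: region weights stochastically greater.

    For a combined sample of at most ``exact_max_n`` values the p-value
    is computed by exhaustive enumeration of all assignments of the
    observed values to the two groups (a permutation distribution of
    the U statistic, which handles ties exactly).  Larger samples use
    the normal approximation with tie correction.
    """
    weights = np.asarray(weights, dtype=float)
    region = sorted(int(i) for i in region)
    n = len(weights)
    if any(i < 0 or i >= n for i in region):
        raise ValueError("region indices out of range")
    complement = sorted(set(range(n)) - set(region))
    if not region or not complement:
        raise ValueError("both the region and its complement must be non-empty")
    a, b = weights[region], weights[complement]
    u_obs = _u_statistic(a, b)

    if n <= exact_max_n:
        n_a = len(a)
        count = 0
        for subset in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            if _u_statistic(weights[mask], weights[~mask]) >= u_obs:
                count += 1
        p = count / comb(n, n_a)
    else:
        from scipy.stats import mannwhitneyu
        p = float(mannwhitneyu(a, b, alternative="greater",
                               method="asymptotic").pvalue)
    raw = weights if raw_weights is None else np.asarray(raw_weights, float)
    return SubstructureTest(
        region=tuple(region), complement=tuple(complement),
        region_mean=float(a.mean()), complement_mean=float(b.mean()),
        region_mean_raw=float(raw[region].mean()),
        complement_mean_raw=float(raw[complement].mean()),
        p_value=float(p), significant=bool(p < 0.05), statistic=u_obs)


def region_from_smarts(smiles: str, smarts: str) -> list[int]:
    """Atom indices matched by a SMARTS pattern (union over matches)."""
    mol = Chem.MolFromSmiles(smiles)
    patt = Chem.MolFromSmarts(smarts)
    if mol is None or patt is None:
        raise ValueError("invalid SMILES or SMARTS")
    return sorted({a for match in mol.GetSubstructMatches(patt)
                   for a in match})


def render_attribution(attribution: AtomAttribution, out_prefix: str) -> dict:
    """Write an SVG atom-weight map and a per-atom CSV table.

    Color intensity is proportional to the normalized weight.  If
    drawing fails the CSV is still written.  Returns the paths written.
    """
    import csv

    mol = Chem.MolFromSmiles(attribution.canonical_smiles)
    paths = {}
    csv_path = f"{out_prefix}_weights.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["atom_index", "element", "raw_weight",
                         "normalized_weight", "key_atom"])
        for i, atom in enumerate(mol.GetAtoms()):
            writer.writerow([i, atom.GetSymbol(),
                             f"{attribution.raw_weights[i]:.6g}",
                             f"{attribution.normalized_weights[i]:.6g}",
                             int(i in attribution.key_atoms)])
    paths["table"] = csv_path
    try:
        from rdkit.Chem.Draw import rdMolDraw2D
        drawer = rdMolDraw2D.MolDraw2DSVG(420, 360)
        colors = {i: (1.0 - 0.85 * w, 1.0, 1.0 - 0.85 * w)  # white -> green
                  for i, w in enumerate(attribution.normalized_weights)}
        rdMolDraw2D.PrepareAndDrawMolecule(
            drawer, mol, highlightAtoms=list(range(mol.GetNumAtoms())),
            highlightAtomColors=colors)
        drawer.FinishDrawing()
        svg_path = f"{out_prefix}.svg"
        with open(svg_path, "w") as fh:
            fh.write(drawer.GetDrawingText())
        paths["svg"] = svg_path
    except Exception:   # drawing backends vary; the table is the contract
        pass
    return paths
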