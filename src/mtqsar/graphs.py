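"""Molecule -> attributed graph conversion for the attentive network.

Atoms become nodes carrying a fixed-width feature vector (element
one-hot, degree, formal charge, hybridization, aromaticity, attached
hydrogens, chirality tag); bonds become *directed* edge pairs carrying
bond-type / conjugation / ring / stereo features.  Hydrogens stay
implicit.  Stereochemistry is encoded so that enantiomers and cis/trans
isomers produce different feature tensors.

The default schema follows the canonical attentive-fingerprint
featurization (39 atom features, 10 bond features); widths are declared
on the schema so alternative vocabularies can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json

import numpy as np
from rdkit import Chem

__all__ = ["FeatureSchema", "MolecularGraph", "BatchedGraph", "mol_to_graph",
           "batch_graphs", "unbatch_graphs"]


def _one_hot(value, choices, other: bool = True) -> list[float]:
    vec = [float(value == c) for c in choices]
    if other:
        vec.append(float(value not in choices))
    return vec


@dataclass(frozen=True)
class FeatureSchema:
    """Declarative atom/bond feature blocks with fixed widths."""

    elements: tuple = ("B", "C", "N", "O", "F", "Si", "P", "S",
                       "Cl", "As", "Se", "Br", "Te", "I", "At")
    degrees: tuple = (0, 1, 2, 3, 4, 5)
    hybridizations: tuple = (
        Chem.HybridizationType.SP, Chem.HybridizationType.SP2,
        Chem.HybridizationType.SP3, Chem.HybridizationType.SP3D,
        Chem.HybridizationType.SP3D2)
    n_hydrogens: tuple = (0, 1, 2, 3, 4)
    chiral_tags: tuple = (Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                          Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    bond_types: tuple = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
                         Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)
    bond_stereo: tuple = (Chem.BondStereo.STEREONONE, Chem.BondStereo.STEREOANY,
                          Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE)

    @property
    def atom_width(self) -> int:
        return (len(self.elements) + 1 + len(self.degrees) + 1 + 1 +
                len(self.hybridizations) + 1 + 1 + len(self.n_hydrogens) + 1 +
                len(self.chiral_tags) + 1)

    @property
    def bond_width(self) -> int:
        return len(self.bond_types) + 1 + 2 + len(self.bond_stereo) + 1

    def atom_vector(self, atom: Chem.Atom) -> list[float]:
        vec = _one_hot(atom.GetSymbol(), self.elements)
        vec += _one_hot(atom.GetDegree(), self.degrees)
        vec.append(float(atom.GetFormalCharge()))
        vec += _one_hot(atom.GetHybridization(), self.hybridizations)
        vec.append(float(atom.GetIsAromatic()))
        vec += _one_hot(atom.GetTotalNumHs(), self.n_hydrogens)
        vec += _one_hot(atom.GetChiralTag(), self.chiral_tags)
        return vec

    def bond_vector(self, bond: Chem.Bond) -> list[float]:
        vec = _one_hot(bond.GetBondType(), self.bond_types)
        vec.append(float(bond.GetIsConjugated()))
        vec.append(float(bond.IsInRing()))
        vec += _one_hot(bond.GetStereo(), self.bond_stereo)
        return vec

    def fingerprint(self) -> str:
        """Stable hash identifying the schema (stored in checkpoints)."""
        payload = json.dumps({
            "elements": self.elements, "degrees": self.degrees,
            "hybridizations": [str(h) for h in self.hybridizations],
            "n_hydrogens": self.n_hydrogens,
            "chiral_tags": [str(t) for t in self.chiral_tags],
            "bond_types": [str(b) for b in self.bond_types],
            "bond_stereo": [str(s) for s in self.bond_stereo],
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MolecularGraph:
    """One molecule as node/edge feature arrays with directed edges."""

    n_atoms: int
    atom_features: np.ndarray          # (n_atoms, F_a)
    edges: np.ndarray                  # (n_edges, 2) directed (src, dst)
    bond_features: np.ndarray          # (n_edges, F_b)
    smiles: str = ""

    @property
    def neighbor_sets(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for src, dst in self.edges:
            nbrs[int(dst)].append(int(src))
        return nbrs


@dataclass
class BatchedGraph:
    """Disjoint union of graphs with per-atom molecule membership."""

    n_atoms: int
    n_mols: int
    atom_features: np.ndarray
    edges: np.ndarray                  # global atom indices
    bond_features: np.ndarray
    mol_index: np.ndarray              # (n_atoms,) molecule id per atom
    sizes: np.ndarray = field(default=None)  # atoms per molecule


def mol_to_graph(smiles: str, schema: FeatureSchema | None = None) -> MolecularGraph:
    """Convert a SMILES string into an attributed molecular graph.

    Both directions of every bond are stored, so neighbor attention can
    treat incoming edges uniformly.
    """
    schema = schema or FeatureSchema()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse structure: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    atom_feats = np.array([schema.atom_vector(a) for a in mol.GetAtoms()],
                          dtype=np.float64).reshape(mol.GetNumAtoms(),
                                                    schema.atom_width)
    edges, bond_feats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bv = schema.bond_vector(bond)
        edges.extend([(i, j), (j, i)])
        bond_feats.extend([bv, bv])
    edges_arr = (np.array(edges, dtype=np.intp) if edges
                 else np.zeros((0, 2), dtype=np.intp))
    bond_arr = (np.array(bond_feats, dtype=np.float64) if bond_feats
                else np.zeros((0, schema.bond_width)))
    return MolecularGraph(n_atoms=mol.GetNumAtoms(), atom_features=atom_feats,
                          edges=edges_arr, bond_features=bond_arr, smiles=smiles)


def batch_graphs(graphs: list[MolecularGraph]) -> BatchedGraph:
    """Disjoint union preserving molecule order; raises on schema mismatch."""
    if not graphs:
        raise ValueError("cannot batch zero graphs")
    fa = graphs[0].atom_features.shape[1]
    fb = graphs[0].bond_features.shape[1]
    for g in graphs:
        if g.atom_features.shape[1] != fa or g.bond_features.shape[1] != fb:
            raise ValueError("feature schema mismatch across batch")
    sizes = np.array([g.n_atoms for g in graphs], dtype=np.intp)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    atom_features = np.vstack([g.atom_features for g in graphs])
    edges = np.vstack([g.edges + off for g, off in zip(graphs, offsets)]) \
        if any(len(g.edges) for g in graphs) else np.zeros((0, 2), dtype=np.intp)
    bond_features = np.vstack([g.bond_features for g in graphs]) \
        if any(len(g.bond_features) for g in graphs) else np.zeros((0, fb))
    mol_index = np.repeat(np.arange(len(graphs), dtype=np.intp), sizes)
    return BatchedGraph(n_atoms=int(sizes.sum()), n_mols=len(graphs),
                        atom_features=atom_features, edges=edges,
                        bond_features=bond_features, mol_index=mol_index,
                        sizes=sizes)


def unbatch_graphs(batch: BatchedGraph) -> list[MolecularGraph]:
    """Inverse of :func:`batch_graphs` (round-trips exactly)."""
    graphs = []
    offsets = np.concatenate([[0], np.cumsum(batch.sizes)])
    for m in range(batch.n_mols):
        lo, hi = offsets[m], offsets[m + 1]
        sel = np.all((batch.edges >= lo) & (batch.edges < hi), axis=1) \
            if len(batch.edges) else np.zeros(0, dtype=bool)
        graphs.append(MolecularGraph(
            n_atoms=int(hi - lo),
            atom_features=batch.atom_features[lo:hi],
            edges=batch.edges[sel] - lo,
            bond_features=batch.bond_features[sel]))
    return graphs
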