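"""Raw activity-table ingestion and curation.

Takes multi-source rows of (SMILES, target, IC50 in nM), standardizes
structures (normalization, largest-fragment desalting, charge
neutralization), merges duplicates by canonical SMILES keeping the
lowest IC50 per target, converts to pIC50 on the molar scale, and
assigns a seeded random train/validation/test split.

pIC50 convention: IC50 is stored in nanomolar, so
``pIC50 = 9 - log10(IC50/nM) = -log10(IC50/M)``.  A 1 uM activity
threshold therefore sits at pIC50 = 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = ["RawActivityRow", "CompoundRecord", "DatasetSplit",
           "CurationReport", "standardize", "merge_duplicates",
           "ic50_to_pic50", "split_dataset", "build_task_table",
           "curate_table", "read_raw_csv", "read_raw_sdf",
           "write_curated_csv", "read_curated_csv"]


@dataclass(frozen=True)
class RawActivityRow:
    source_id: str
    smiles: str
    target: str
    ic50_nM: float

    def __post_init__(self):
        if not (self.ic50_nM > 0):
            raise ValueError("IC50 must be a positive nanomolar value")


@dataclass
class CompoundRecord:
    canonical_smiles: str
    activities: dict = field(default_factory=dict)  # target -> pIC50
    split: str = "unassigned"


@dataclass(frozen=True)
class DatasetSplit:
    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError("need three non-negative ratios")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass
class CurationReport:
    n_rows_in: int = 0
    n_rows_kept: int = 0
    n_rejected: int = 0
    n_compounds: int = 0
    rejections: list = field(default_factory=list)  # (smiles, reason)

    def __str__(self):
        lines = [f"rows in:        {self.n_rows_in}",
                 f"rows kept:      {self.n_rows_kept}",
                 f"rows rejected:  {self.n_rejected}",
                 f"unique compounds: {self.n_compounds}"]
        for smi, reason in self.rejections[:50]:
            lines.append(f"  rejected {smi!r}: {reason}")
        return "\n".join(lines)


_fragment_chooser = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def standardize(smiles: str) -> str:
    """Canonicalize a structure: normalize, desalt, neutralize charge.

    Returns the canonical SMILES of the parent molecule.  Idempotent:
    re-standardizing the output reproduces it.  Raises ``ValueError``
    on unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


def ic50_to_pic50(ic50_nM: float) -> float:
    """pIC50 = 9 - log10(IC50/nM); strictly decreasing in IC50."""
    if not (ic50_nM > 0):
        raise ValueError("IC50 must be positive")
    return 9.0 - math.log10(ic50_nM)


def merge_duplicates(rows: list[RawActivityRow]) -> list[CompoundRecord]:
    """One record per canonical SMILES; per target keep the lowest IC50.

    The minimum is taken on the nanomolar scale before pIC50 conversion:
    among duplicated measurements the most potent one (lowest IC50,
    highest pIC50) is retained.
    """
    best: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for row in rows:
        if row.smiles not in best:
            best[row.smiles] = {}
            order.append(row.smiles)
        per_target = best[row.smiles]
        prev = per_target.get(row.target)
        if prev is None or row.ic50_nM < prev:
            per_target[row.target] = row.ic50_nM
    return [CompoundRecord(canonical_smiles=smi,
                           activities={t: ic50_to_pic50(v)
                                       for t, v in best[smi].items()})
            for smi in order]


def split_dataset(records: list[CompoundRecord],
                  spec: DatasetSplit = DatasetSplit()) -> list[CompoundRecord]:
    """Seeded random 8:1:1 (by default) partition, in place.

    Validation and test sizes are their ratio shares rounded to the
    nearest integer; the remainder goes to training, so partitions are
    disjoint and exhaustive.
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    n_valid = int(round(n * spec.ratios[1]))
    n_test = int(round(n * spec.ratios[2]))
    perm = np.random.default_rng(spec.seed).permutation(n)
    for i in perm[:n_valid]:
        records[i].split = "valid"
    for i in perm[n_valid:n_valid + n_test]:
        records[i].split = "test"
    for i in perm[n_valid + n_test:]:
        records[i].split = "train"
    return records


def build_task_table(records: list[CompoundRecord],
                     targets: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Label matrix (n, T) of pIC50 with a parallel boolean mask.

    Mask is true iff the activity exists; absent entries hold NaN.
    """
    known = set()
    for rec in records:
        known.update(rec.activities)
    unknown = known - set(targets)
    if unknown:
        raise ValueError(f"records carry unknown targets: {sorted(unknown)}")
    labels = np.full((len(records), len(targets)), np.nan)
    mask = np.zeros((len(records), len(targets)), dtype=bool)
    for i, rec in enumerate(records):
        for j, t in enumerate(targets):
            if t in rec.activities:
                labels[i, j] = rec.activities[t]
                mask[i, j] = True
    return labels, mask


def curate_table(rows: list[RawActivityRow],
                 split: DatasetSplit = DatasetSplit()
                 ) -> tuple[list[CompoundRecord], CurationReport]:
    """Full curation: standardize, merge, convert, split, report."""
    report = CurationReport(n_rows_in=len(rows))
    clean_rows = []
    for row in rows:
        try:
            canonical = standardize(row.smiles)
        except ValueError as exc:
            report.n_rejected += 1
            report.rejections.append((row.smiles, str(exc)))
            logger.info("dropped row %s: %s", row.source_id, exc)
            continue
        clean_rows.append(RawActivityRow(row.source_id, canonical,
                                         row.target, row.ic50_nM))
    report.n_rows_kept = len(clean_rows)
    records = merge_duplicates(clean_rows)
    report.n_compounds = len(records)
    if len(records) >= 3:
        split_dataset(records, split)
    return records, report


# -- CSV io -------------------------------------------------------------

def read_raw_csv(path: str, targets: list[str]) -> list[RawActivityRow]:
    """Read a wide CSV: `smiles` column + one `<target>_ic50_nM` per target."""
    df = pd.read_csv(path)
    rows = []
    for i, r in df.iterrows():
        for t in targets:
            col = f"{t}_ic50_nM"
            if col in df.columns and pd.notna(r[col]):
                rows.append(RawActivityRow(str(i), str(r["smiles"]), t,
                                           float(r[col])))
    return rows


def read_raw_sdf(path: str, property_map: dict) -> list[RawActivityRow]:
    """Read an SDF where ``property_map`` maps target name -> SD property
    holding the IC50 in nM; molecules missing a property are skipped for
    that target."""
    rows = []
    supplier = Chem.SDMolSupplier(path)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        smi = Chem.MolToSmiles(mol)
        for target, prop in property_map.items():
            if mol.HasProp(prop):
                try:
                    value = float(mol.GetProp(prop))
                except ValueError:
                    continue
                if value > 0:
                    rows.append(RawActivityRow(f"sdf-{i}", smi, target, value))
    return rows


def records_to_frame(records: list[CompoundRecord],
                     targets: list[str]) -> pd.DataFrame:
    data = {"canonical_smiles": [r.canonical_smiles for r in records],
            "split": [r.split for r in records]}
    for t in targets:
        data[f"pIC50_{t}"] = [r.activities.get(t, np.nan) for r in records]
    return pd.DataFrame(data)


def write_curated_csv(records: list[CompoundRecord], targets: list[str],
                      path: str) -> None:
    records_to_frame(records, targets).to_csv(path, index=False)


def read_curated_csv(path: str) -> tuple[list[CompoundRecord], list[str]]:
    df = pd.read_csv(path)
    targets = [c[len("pIC50_"):] for c in df.columns if c.startswith("pIC50_")]
    records = []
    for _, r in df.iterrows():
        acts = {t: float(r[f"pIC50_{t}"]) for t in targets
                if pd.notna(r[f"pIC50_{t}"])}
        records.append(CompoundRecord(canonical_smiles=r["canonical_smiles"],
                                      activities=acts, split=r["split"]))
    return records, targets
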