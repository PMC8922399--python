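"""Curate a raw multi-source activity table.

Builds a tiny raw table in memory (duplicate molecules, a salt form, a
broken row), standardizes and deduplicates it, converts IC50 (nM) to
pIC50, and assigns the 8:1:1-style split.
"""

from mtqsar.curation import DatasetSplit, RawActivityRow, curate_table

rows = [
    RawActivityRow("db1-001", "CC(=O)Nc1ccc(O)cc1", "JAK1", 120.0),
    RawActivityRow("db2-104", "Oc1ccc(NC(C)=O)cc1", "JAK1", 85.0),   # same molecule, lower IC50 wins
    RawActivityRow("db1-002", "CC(=O)Nc1ccc(O)cc1", "JAK2", 540.0),
    RawActivityRow("db3-77", "c1ccc2nc(N3CCNCC3)ncc2c1.Cl", "JAK1", 15.0),  # salt form
    RawActivityRow("db3-78", "this_is_not_a_molecule", "JAK3", 1.0),        # rejected
    RawActivityRow("db1-003", "Nc1ncnc2[nH]ccc12", "TYK2", 2300.0),
]

records, report = curate_table(rows, DatasetSplit(seed=0))
print(report)
print()
for rec in records:
    acts = {t: round(v, 2) for t, v in rec.activities.items()}
    print(f"{rec.canonical_smiles:42s} {acts}")

# The duplicate pair collapses to one record keeping the more potent
# measurement (85 nM -> pIC50 7.07); the salt loses its counterion; the
# unparseable row is dropped and listed in the report.
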