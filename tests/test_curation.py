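import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtqsar.curation import (CompoundRecord, DatasetSplit, RawActivityRow,
                             build_task_table, curate_table, ic50_to_pic50,
                             merge_duplicates, split_dataset, standardize)


class TestStandardize:
    def test_idempotent(self):
        once = standardize("CCO")
        assert standardize(once) == once

    def test_desalting_keeps_largest_organic_fragment(self):
        assert "." not in standardize("CCN.Cl")
        assert standardize("CCN.Cl") == standardize("CCN")

    def test_charge_neutralization(self):
        assert standardize("CC[NH3+].[Cl-]") == standardize("CCN")

    def test_equivalent_forms_map_to_one_string(self):
        assert standardize("OCC") == standardize("CCO")

    def test_rejects_unparseable(self):
        with pytest.raises(ValueError):
            standardize("not_a_smiles")


class TestPic50:
    @pytest.mark.parametrize("ic50,expected", [
        (1.0, 9.0),                      # 1 nM
        (1000.0, 6.0),                   # the 1 uM activity threshold
        (767000.0, 9 - math.log10(767000.0)),   # ~3.115, dataset maximum
    ])
    def test_unit_convention(self, ic50, expected):
        assert ic50_to_pic50(ic50) == pytest.approx(expected, abs=1e-12)

    def test_maximum_value_matches_hand_log(self):
        assert ic50_to_pic50(767000.0) == pytest.approx(3.1152, abs=5e-5)

    @given(st.floats(min_value=1e-6, max_value=1e9))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_and_monotonicity(self, ic50):
        p = ic50_to_pic50(ic50)
        assert 10 ** (9 - p) == pytest.approx(ic50, rel=1e-9)
        assert ic50_to_pic50(ic50 * 2) < p

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ic50_to_pic50(0.0)


class TestMergeDuplicates:
    def test_lower_ic50_kept_per_target(self):
        rows = [RawActivityRow("a", "CCO", "JAK1", 10.0),
                RawActivityRow("b", "CCO", "JAK1", 5.0)]
        (rec,) = merge_duplicates(rows)
        assert rec.activities["JAK1"] == pytest.approx(ic50_to_pic50(5.0))

    def test_multi_target_rows_merge_into_one_record(self):
        rows = [RawActivityRow("a", "CCO", "JAK1", 5.0),
                RawActivityRow("b", "CCO", "JAK2", 50.0)]
        (rec,) = merge_duplicates(rows)
        assert set(rec.activities) == {"JAK1", "JAK2"}

    def test_grouping_matches_brute_force(self):
        rng = np.random.default_rng(3)
        smis = ["CCO", "CCN", "CCC"]
        rows = [RawActivityRow(str(i), smis[rng.integers(3)],
                               ["JAK1", "JAK2"][rng.integers(2)],
                               float(rng.uniform(1, 100)))
                for i in range(40)]
        records = {r.canonical_smiles: r for r in merge_duplicates(rows)}
        for smi in smis:
            for t in ("JAK1", "JAK2"):
                expect = [r.ic50_nM for r in rows
                          if r.smiles == smi and r.target == t]
                if expect:
                    assert records[smi].activities[t] == pytest.approx(
                        ic50_to_pic50(min(expect)))

    def test_empty_input(self):
        assert merge_duplicates([]) == []


class TestSplit:
    def _records(self, n):
        return [CompoundRecord(canonical_smiles=f"C{'C' * (i % 7)}N{i}")
                for i in range(n)]

    def test_sizes_80_10_10(self):
        recs = split_dataset(self._records(100), DatasetSplit(seed=1))
        counts = {s: sum(r.split == s for r in recs)
                  for s in ("train", "valid", "test")}
        assert counts == {"train": 80, "valid": 10, "test": 10}

    def test_rounding_remainder_goes_to_train(self):
        recs = split_dataset(self._records(13898), DatasetSplit(seed=0))
        counts = {s: sum(r.split == s for r in recs)
                  for s in ("train", "valid", "test")}
        assert counts == {"train": 11118, "valid": 1390, "test": 1390}

    def test_deterministic_and_exhaustive(self):
        a = [r.split for r in split_dataset(self._records(50),
                                            DatasetSplit(seed=9))]
        b = [r.split for r in split_dataset(self._records(50),
                                            DatasetSplit(seed=9))]
        assert a == b
        assert set(a) <= {"train", "valid", "test"}
        assert all(s != "unassigned" for s in a)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_dataset(self._records(2))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            DatasetSplit(ratios=(0.5, 0.2, 0.2))


class TestTaskTable:
    def test_mask_pattern(self):
        recs = [CompoundRecord("CCO", {"JAK1": 7.0, "JAK2": 6.0,
                                       "JAK3": 5.0, "TYK2": 8.0}),
                CompoundRecord("CCN", {"JAK1": 6.5})]
        targets = ["JAK1", "JAK2", "JAK3", "TYK2"]
        labels, mask = build_task_table(recs, targets)
        assert mask[0].all()
        assert mask[1].tolist() == [True, False, False, False]
        assert np.isnan(labels[1, 1])

    def test_column_counts_match_record_counts(self):
        rng = np.random.default_rng(0)
        targets = ["JAK1", "JAK2", "JAK3", "TYK2"]
        recs = []
        for i in range(30):
            acts = {t: 6.0 for t in targets if rng.random() > 0.5}
            recs.append(CompoundRecord(f"C{i}", acts))
        _, mask = build_task_table(recs, targets)
        for j, t in enumerate(targets):
            assert mask[:, j].sum() == sum(t in r.activities for r in recs)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            build_task_table([CompoundRecord("CCO", {"XXX": 5.0})], ["JAK1"])


def test_sdf_reader_maps_named_properties(tmp_path):
    from rdkit import Chem
    from mtqsar.curation import read_raw_sdf
    path = str(tmp_path / "mols.sdf")
    writer = Chem.SDWriter(path)
    m1 = Chem.MolFromSmiles("CCO")
    m1.SetProp("IC50_JAK1_nM", "12.5")
    m1.SetProp("IC50_JAK2_nM", "40")
    m2 = Chem.MolFromSmiles("c1ccncc1")
    m2.SetProp("IC50_JAK1_nM", "7")
    writer.write(m1)
    writer.write(m2)
    writer.close()
    rows = read_raw_sdf(path, {"JAK1": "IC50_JAK1_nM",
                               "JAK2": "IC50_JAK2_nM"})
    assert len(rows) == 3
    assert {(r.target, r.ic50_nM) for r in rows} == {
        ("JAK1", 12.5), ("JAK2", 40.0), ("JAK1", 7.0)}


def test_curate_table_end_to_end_reports_rejections():
    rows = [RawActivityRow("1", "CCO", "JAK1", 5.0),
            RawActivityRow("2", "OCC", "JAK1", 10.0),     # duplicate of CCO
            RawActivityRow("3", "xxxx", "JAK2", 5.0),     # unparseable
            RawActivityRow("4", "CCN.Cl", "JAK2", 3.0),
            RawActivityRow("5", "c1ccccc1", "JAK1", 2.0)]
    records, report = curate_table(rows, DatasetSplit(seed=0))
    assert report.n_rows_in == 5
    assert report.n_rejected == 1
    assert report.n_compounds == 3
    by_smiles = {r.canonical_smiles: r for r in records}
    assert by_smiles[standardize("CCO")].activities["JAK1"] == pytest.approx(
        ic50_to_pic50(5.0))   # the lower IC50 of the duplicate pair
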