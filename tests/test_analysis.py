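import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from segrel import analysis
from segrel.mask_io import GridMismatchError, LabelMask, SegmentationRecord
from segrel.analysis import (
    COMPARISON_LABELS,
    assemble_study_table,
    good_dc_fraction,
    kruskal_by_type,
    kruskal_wallis,
    mean_pair_volume,
    merge_lesions_per_femur,
    overall_summary,
    pooled_mean,
    split_by_size,
    summarize,
    summarize_by_type,
    write_report,
)
from .conftest import ball_mask


def _table(rows):
    """Study-table DataFrame from (femur, type, kind, label, dice, mean_vol)."""
    recs = []
    for femur, ltype, kind, label, dice, vol in rows:
        recs.append(
            {
                "femur_id": femur,
                "lesion_type": ltype,
                "kind": kind,
                "label": label,
                "dice": dice,
                "volume_a": vol,
                "volume_b": vol,
                "volume_intersection": dice * vol,
                "non_overlap_volume": 2 * vol * (1 - dice),
                "mean_volume": vol,
            }
        )
    return pd.DataFrame(recs)


class TestMergeLesions:
    def test_single_mask_identity(self):
        m = ball_mask((12, 12, 12), (6, 6, 6), 3)
        out = merge_lesions_per_femur([m])
        assert np.array_equal(out.voxels, m.voxels)

    def test_disjoint_lesions_union(self):
        a = LabelMask(np.zeros((10, 10, 10), dtype=bool), (1, 1, 1))
        b = LabelMask(np.zeros((10, 10, 10), dtype=bool), (1, 1, 1))
        a.voxels[:1, :2, :5] = True  # 10 voxels
        b.voxels[5:, 8:, 8:] = True  # 20 voxels
        out = merge_lesions_per_femur([a, b])
        assert out.n_voxels == 30

    def test_grid_mismatch_rejected(self):
        a = LabelMask(np.zeros((10, 10, 10), dtype=bool), (1, 1, 1))
        b = LabelMask(np.zeros((10, 10, 10), dtype=bool), (1, 1, 2))
        with pytest.raises(GridMismatchError):
            merge_lesions_per_femur([a, b])


def _records_for_femur(femur_id, lesion_type, masks):
    """masks: dict (operator, session) -> LabelMask."""
    return [
        SegmentationRecord(femur_id, op, ses, lesion_type, mask)
        for (op, ses), mask in masks.items()
    ]


class TestAssembleStudyTable:
    def test_tiny_cohort_shape(self, tiny_cohort):
        records, _ = tiny_cohort
        table = assemble_study_table(records)
        assert len(table) == 6 * 4
        for femur, sub in table.groupby("femur_id"):
            assert sorted(sub["label"]) == sorted(COMPARISON_LABELS)

    def test_pairing_definition(self, tiny_cohort):
        records, _ = tiny_cohort
        by_key = {(r.femur_id, r.operator, r.session): r for r in records}
        table = assemble_study_table(records)
        femur = table["femur_id"].iloc[0]
        from segrel.metrics import mask_volume

        row = table[(table["femur_id"] == femur) & (table["label"] == "inter@2")].iloc[0]
        assert row["volume_a"] == pytest.approx(
            mask_volume(by_key[(femur, "I", 2)].mask)
        )
        assert row["volume_b"] == pytest.approx(
            mask_volume(by_key[(femur, "II", 2)].mask)
        )
        row = table[(table["femur_id"] == femur) & (table["label"] == "intra@I")].iloc[0]
        assert row["volume_b"] == pytest.approx(
            mask_volume(by_key[(femur, "I", 2)].mask)
        )

    def test_incomplete_femur_contributes_no_rows(self, tiny_cohort):
        records, _ = tiny_cohort
        dropped_femur = records[0].femur_id
        partial = [
            r
            for r in records
            if not (r.femur_id == dropped_femur and r.operator == "II" and r.session == 2)
        ]
        table = assemble_study_table(partial)
        assert dropped_femur not in set(table["femur_id"])
        assert len(table) == 5 * 4

    def test_both_empty_pairs_excluded(self, caplog):
        shape, spacing = (8, 8, 8), (1.0, 1.0, 1.0)
        ball = ball_mask(shape, (4, 4, 4), 2, spacing)
        empty = LabelMask(np.zeros(shape, dtype=bool), spacing)
        # operator II segmented nothing in either session: intra@II has both
        # masks empty and is dropped; the inter pairs score Dice 0
        masks = {("I", 1): ball, ("I", 2): ball, ("II", 1): empty, ("II", 2): empty}
        table = assemble_study_table(_records_for_femur("f1", "mixed", masks))
        assert sorted(table["label"]) == ["inter@1", "inter@2", "intra@I"]
        assert table.loc[table["label"] == "inter@1", "dice"].iloc[0] == 0.0


class TestSummaries:
    def test_constant_group_has_zero_sd(self):
        t = _table(
            [(f"f{i}", "mixed", "inter", "inter@1", 0.6, 10.0) for i in range(5)]
        )
        out = summarize_by_type(t)
        assert out["mean_dc"].iloc[0] == pytest.approx(0.6)
        assert out["sd_dc"].iloc[0] == 0.0

    def test_two_value_group_sample_sd(self):
        t = _table(
            [
                ("f1", "mixed", "inter", "inter@1", 0.4, 10.0),
                ("f2", "mixed", "inter", "inter@1", 0.8, 10.0),
            ]
        )
        out = summarize_by_type(t)
        assert out["mean_dc"].iloc[0] == pytest.approx(0.6)
        assert out["sd_dc"].iloc[0] == pytest.approx(0.28284, abs=1e-4)

    def test_partition_identity(self, tiny_cohort):
        """n-weighted per-type means reproduce the overall mean exactly."""
        records, _ = tiny_cohort
        table = assemble_study_table(records)
        per_type = summarize_by_type(table)
        overall = overall_summary(table)
        for label in COMPARISON_LABELS:
            sub = per_type[per_type["label"] == label]
            pooled = pooled_mean(sub["mean_dc"], sub["n"])
            direct = overall.loc[overall["label"] == label, "mean_dc"].iloc[0]
            assert pooled == pytest.approx(direct, abs=1e-12)

    def test_pooled_mean_validates(self):
        with pytest.raises(ValueError):
            pooled_mean([], [])
        with pytest.raises(ValueError):
            pooled_mean([0.5], [0])


class TestMeanPairVolume:
    def test_average_of_pair(self):
        assert mean_pair_volume({"volume_a": 10.0, "volume_b": 30.0}) == 20.0

    def test_equal_volumes(self):
        assert mean_pair_volume({"volume_a": 7.0, "volume_b": 7.0}) == 7.0

    def test_worked_counts(self):
        assert mean_pair_volume({"volume_a": 0.1, "volume_b": 0.06}) == pytest.approx(
            0.08
        )


class TestSplitBySize:
    def test_strata_assignment(self):
        t = _table(
            [
                ("f1", "mixed", "inter", "inter@1", 0.8, 59.0),
                ("f2", "mixed", "inter", "inter@1", 0.6, 61.0),
            ]
        )
        out = split_by_size(t, threshold=60.0)
        assert set(out["stratum"]) == {"large", "small"}
        assert out.loc[out["stratum"] == "large", "n"].iloc[0] == 1

    def test_exactly_at_threshold_goes_to_small(self):
        t = _table([("f1", "mixed", "inter", "inter@1", 0.8, 60.0)])
        out = split_by_size(t, threshold=60.0)
        assert list(out["stratum"]) == ["small"]

    def test_empty_stratum_absent(self):
        t = _table([("f1", "mixed", "intra", "intra@I", 0.8, 10.0)])
        out = split_by_size(t, threshold=60.0)
        assert list(out["kind"]) == ["intra"]
        assert list(out["stratum"]) == ["small"]


class TestGoodDcFraction:
    def test_half_above(self):
        assert good_dc_fraction([0.8, 0.6]) == 0.5

    def test_all_above(self):
        assert good_dc_fraction([0.9, 0.9, 0.9]) == 1.0

    def test_strictly_greater_convention(self):
        assert good_dc_fraction([0.7]) == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            good_dc_fraction([])


def _brute_force_h(groups):
    """Rank-based Kruskal-Wallis H with tie correction, from first principles."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_worked_example_no_ties(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(stats.chi2.sf(7.2, df=2))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_ranks_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 4, size=rng.integers(2, 4))
        groups = [rng.integers(0, 4, size=s).astype(float) for s in sizes]
        if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in (0,)):
            return
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(_brute_force_h(groups), abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(h, df=len(groups) - 1), abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_all_tied_degenerate(self, caplog):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_per_session_tests_marked_primary(self, tiny_cohort):
        records, _ = tiny_cohort
        table = assemble_study_table(records)
        out = kruskal_by_type(table)
        assert set(out.loc[out["primary"], "label"]) == {"inter@1", "inter@2"}
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()


class TestWriteReport:
    def test_json_round_trip_and_csvs(self, tiny_cohort, tmp_path):
        records, _ = tiny_cohort
        table = assemble_study_table(records)
        report = summarize(table)
        paths = write_report(report, tmp_path, table=table)
        doc = json.loads(paths["report"].read_text())
        full = doc["full_precision"]
        assert full["n_femurs"] == 6
        # lossless round trip of the overall means
        overall = {r["label"]: r["mean_dc"] for r in full["overall"]}
        direct = overall_summary(table)
        for label in COMPARISON_LABELS:
            assert overall[label] == direct.loc[direct["label"] == label, "mean_dc"].iloc[0]
        per_type = pd.read_csv(paths["per_type"])
        assert len(per_type) == 4 * 3  # 4 comparison sets x 3 lesion types
        per_femur = pd.read_csv(paths["per_femur"])
        assert len(per_femur) == len(table)

    def test_unavailable_cells_render_na(self, tmp_path):
        t = _table([("f1", "mixed", "inter", "inter@1", 0.8, 10.0)])
        report = summarize(t)
        write_report(report, tmp_path)
        text = (tmp_path / "per_type.csv").read_text()
        assert "NA" in text  # SD of an n=1 group is not a number
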