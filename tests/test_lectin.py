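import io as _io
import math

import numpy as np
import pandas as pd
import pytest

from golgiph import lectin as lc
from golgiph import synthetic_data as sd


def spot_frame(rows):
    return pd.DataFrame(rows, columns=list(lc.SPOT_COLUMNS))


def uniform_table(condition, value, lectins=("L01", "L02"), reps=3, spots=2):
    rows = []
    for r in range(reps):
        for lec in lectins:
            for s in range(spots):
                rows.append((condition, f"{condition}_r{r}", lec, s, value))
    return spot_frame(rows)


class TestAggregate:
    def test_constant_spots(self):
        fps = lc.aggregate(uniform_table("a", 7.0))
        table = fps["a"].table
        assert np.allclose(table["mean"], 7.0)
        assert np.allclose(table["sd"], 0.0)
        assert np.all(table["n"] == 3)

    def test_hand_listed_replicates_match_textbook_formulas(self):
        # six replicate means for one lectin, computed independently below
        values = [102.0, 98.5, 110.2, 95.4, 104.8, 99.1]
        rows = [("a", f"a_r{i}", "L01", 0, v) for i, v in enumerate(values)]
        fp = lc.aggregate(spot_frame(rows))["a"]
        mean = sum(values) / 6.0
        sd_ = math.sqrt(sum((v - mean) ** 2 for v in values) / 5.0)
        row = fp.table.iloc[0]
        assert row["mean"] == pytest.approx(mean, rel=1e-12)
        assert row["sd"] == pytest.approx(sd_, rel=1e-12)
        assert row["n"] == 6

    def test_spots_averaged_within_replicate_first(self):
        rows = [
            ("a", "a_r0", "L01", 0, 10.0), ("a", "a_r0", "L01", 1, 20.0),
            ("a", "a_r1", "L01", 0, 30.0), ("a", "a_r1", "L01", 1, 40.0),
        ]
        fp = lc.aggregate(spot_frame(rows))["a"]
        assert fp.replicate_means["L01"] == pytest.approx([15.0, 35.0])

    def test_unbalanced_replicate_counts_reported(self):
        rows = [("a", f"a_r{i}", "L01", 0, 5.0) for i in range(4)]
        rows += [("a", f"a_r{i}", "L02", 0, 5.0) for i in range(4)]
        fp = lc.aggregate(spot_frame(rows))["a"]
        assert list(fp.table["n"]) == [4, 4]

    def test_missing_lectin_in_replicate_errors_with_gap_list(self):
        rows = [("a", "a_r0", "L01", 0, 5.0), ("a", "a_r0", "L02", 0, 5.0),
                ("a", "a_r1", "L01", 0, 5.0)]
        with pytest.raises(ValueError, match="L02"):
            lc.aggregate(spot_frame(rows))

    def test_invariant_to_spot_order_and_replicate_labels(self, rng):
        spec = sd.LectinArraySpec(panel=lc.default_panel(8), n_replicates=3, n_spots=4)
        spots = sd.gen_lectin_arrays(spec, 5)
        spots_a = spots[spots["condition"] == spec.condition_a]
        shuffled = spots_a.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.assign(
            replicate_id=shuffled["replicate_id"].map(lambda s: "rep_" + s[::-1])
        )
        fp1 = lc.aggregate(spots_a)[spec.condition_a]
        fp2 = lc.aggregate(relabeled)[spec.condition_a]
        t1 = fp1.table.sort_values("lectin").reset_index(drop=True)
        t2 = fp2.table.sort_values("lectin").reset_index(drop=True)
        assert np.allclose(t1["mean"], t2["mean"])
        assert np.allclose(t1["sd"], t2["sd"])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            lc.aggregate(spot_frame([("a", "a_r0", "L01", 0, -1.0)]))


def planted_fingerprints(seed, fold_map, n_lectins=43):
    spec = sd.LectinArraySpec(panel=lc.default_panel(n_lectins), fold_map=fold_map)
    spots = sd.gen_lectin_arrays(spec, seed)
    fps = lc.aggregate(spots)
    return fps[spec.condition_b], fps[spec.condition_a]


class TestSubtract:
    def test_self_comparison_no_significance(self):
        fp = lc.aggregate(uniform_table("a", 9.0, reps=4))["a"]
        import copy

        sf = lc.subtract(fp, copy.deepcopy(fp))
        assert np.allclose(sf.table["delta"], 0.0)
        assert not sf.table["significant"].any()

    def test_antisymmetry(self):
        fa, fb = planted_fingerprints(11, {"L03": 2.0, "L07": 0.5}, n_lectins=12)
        ab = lc.subtract(fa, fb)
        ba = lc.subtract(fb, fa)
        assert np.allclose(ab.table["delta"], -ba.table["delta"])
        assert np.allclose(ab.table["p_value"], ba.table["p_value"])

    def test_planted_twofold_detected(self):
        fa, fb = planted_fingerprints(2, {"L05": 2.0})
        sf = lc.subtract(fa, fb)
        row = sf.table[sf.table["lectin"] == "L05"].iloc[0]
        assert row["significant"]
        assert row["delta"] > 0
        assert row["signed_fold_change"] == pytest.approx(2.0, rel=0.2)

    def test_decrease_reported_as_negative_fold_above_one_magnitude(self):
        fa, fb = planted_fingerprints(3, {"L05": 0.5})
        sf = lc.subtract(fa, fb)
        row = sf.table[sf.table["lectin"] == "L05"].iloc[0]
        assert row["delta"] < 0
        assert row["signed_fold_change"] < 0
        assert abs(row["signed_fold_change"]) == pytest.approx(2.0, rel=0.2)

    def test_fold_sign_matches_delta_sign_everywhere(self):
        fa, fb = planted_fingerprints(4, {"L01": 3.0, "L02": 0.3})
        sf = lc.subtract(fa, fb)
        nonzero = sf.table[sf.table["delta"] != 0]
        assert np.all(np.sign(nonzero["delta"]) == np.sign(nonzero["signed_fold_change"]))

    def test_zero_denominator_flags_fold_keeps_delta(self):
        fa = lc.aggregate(uniform_table("a", 5.0, reps=3))["a"]
        fb = lc.aggregate(uniform_table("b", 0.0, reps=3))["b"]
        fb.condition = "b"
        sf = lc.subtract(fa, fb)
        assert np.allclose(sf.table["delta"], 5.0)
        assert sf.table["signed_fold_change"].isna().all()

    def test_panel_mismatch_rejected(self):
        fa = lc.aggregate(uniform_table("a", 5.0, lectins=("L01", "L02")))["a"]
        fb = lc.aggregate(uniform_table("b", 5.0, lectins=("L01", "L03")))["b"]
        with pytest.raises(ValueError):
            lc.subtract(fa, fb)

    def test_bh_correction_is_more_conservative(self):
        fa, fb = planted_fingerprints(6, {"L01": 1.25})
        raw = lc.subtract(fa, fb)
        bh = lc.subtract(fa, fb, correction="bh")
        assert bh.significant_lectins <= raw.significant_lectins


class TestIntersectPairs:
    def test_planted_common_and_concordant_sets(self):
        # pair1: L01+, L02+, L03+, L04-, L05+, L06-  (all significant)
        # pair2: L01+, L02+, L03-, L04+, L07+        (all significant)
        # common = {L01, L02, L03, L04}; concordant = {L01, L02}
        fold1 = {"L01": 2.0, "L02": 2.0, "L03": 2.0, "L04": 0.5, "L05": 2.0, "L06": 0.5}
        fold2 = {"L01": 2.0, "L02": 2.0, "L03": 0.5, "L04": 2.0, "L07": 2.0}
        fa1, fb1 = planted_fingerprints(21, fold1, n_lectins=20)
        fa2, fb2 = planted_fingerprints(22, fold2, n_lectins=20)
        sf1 = lc.subtract(fa1, fb1)
        sf2 = lc.subtract(fa2, fb2)
        # guard: the planted effects must all be significant for the oracle
        assert set(fold1) <= sf1.significant_lectins
        assert set(fold2) <= sf2.significant_lectins
        cross = lc.intersect_pairs(sf1, sf2)
        spurious = (sf1.significant_lectins - set(fold1)) | (
            sf2.significant_lectins - set(fold2)
        )
        assert set(cross.common_significant) - spurious == {"L01", "L02", "L03", "L04"}
        assert set(cross.concordant) - spurious == {"L01", "L02"}

    def test_disjoint_significant_sets_empty_common(self):
        fa1, fb1 = planted_fingerprints(31, {"L01": 3.0}, n_lectins=6)
        fa2, fb2 = planted_fingerprints(32, {"L04": 3.0}, n_lectins=6)
        sf1 = lc.subtract(fa1, fb1)
        sf2 = lc.subtract(fa2, fb2)
        sf1.table.loc[~sf1.table["lectin"].isin(["L01"]), "significant"] = False
        sf2.table.loc[~sf2.table["lectin"].isin(["L04"]), "significant"] = False
        cross = lc.intersect_pairs(sf1, sf2)
        assert cross.common_significant == ()
        assert cross.concordant == ()

    def test_identical_fingerprints_all_concordant(self):
        fa, fb = planted_fingerprints(33, {"L02": 2.0, "L05": 0.4}, n_lectins=10)
        sf = lc.subtract(fa, fb)
        cross = lc.intersect_pairs(sf, sf)
        assert set(cross.common_significant) == sf.significant_lectins
        assert cross.concordant == cross.common_significant

    def test_concordant_subset_of_common(self):
        fa1, fb1 = planted_fingerprints(34, {"L01": 2.0, "L02": 0.5}, n_lectins=15)
        fa2, fb2 = planted_fingerprints(35, {"L01": 0.5, "L02": 0.5}, n_lectins=15)
        cross = lc.intersect_pairs(lc.subtract(fa1, fb1), lc.subtract(fa2, fb2))
        assert set(cross.concordant) <= set(cross.common_significant)

    def test_panel_mismatch_rejected(self):
        fa1, fb1 = planted_fingerprints(36, {}, n_lectins=5)
        fa2, fb2 = planted_fingerprints(37, {}, n_lectins=6)
        with pytest.raises(ValueError):
            lc.intersect_pairs(lc.subtract(fa1, fb1), lc.subtract(fa2, fb2))


class TestHeatmapOrder:
    def make_fps(self, means_by_condition):
        fps = {}
        for cond, means in means_by_condition.items():
            rows = []
            for i, m in enumerate(means):
                for r in range(2):
                    rows.append((cond, f"{cond}_r{r}", f"L{i + 1:02d}", 0, m))
            fps[cond] = lc.aggregate(spot_frame(rows))[cond]
        return fps

    def test_already_sorted_reference_unchanged(self):
        fps = self.make_fps({"ref": [30.0, 20.0, 10.0]})
        order, matrix = lc.heatmap_order(fps, "ref")
        assert order == ("L01", "L02", "L03")

    def test_permuted_input_sorted_by_reference_rank(self, rng):
        means = list(rng.uniform(1, 100, 12))
        fps = self.make_fps({"ref": means, "other": list(rng.uniform(1, 100, 12))})
        order, matrix = lc.heatmap_order(fps, "ref")
        expected = [f"L{i + 1:02d}" for i in np.argsort(-np.asarray(means), kind="stable")]
        assert list(order) == expected
        assert list(matrix.index) == expected
        assert set(matrix.columns) == {"ref", "other"}

    def test_ties_preserve_panel_order(self):
        fps = self.make_fps({"ref": [10.0, 50.0, 10.0]})
        order, _ = lc.heatmap_order(fps, "ref")
        assert order == ("L02", "L01", "L03")

    def test_missing_reference_rejected(self):
        fps = self.make_fps({"a": [1.0, 2.0]})
        with pytest.raises(KeyError):
            lc.heatmap_order(fps, "zzz")


class TestRadarExport:
    def test_zero_deltas_sit_on_baseline(self):
        fp = lc.aggregate(uniform_table("a", 9.0, reps=4))["a"]
        import copy

        sf = lc.subtract(fp, copy.deepcopy(fp))
        table = lc.radar_export(sf)
        assert np.allclose(table["delta"], 0.0)
        assert np.allclose(table["baseline"], 0.0)

    def test_row_count_matches_panel(self):
        fa, fb = planted_fingerprints(41, {"L01": 2.0}, n_lectins=43)
        table = lc.radar_export(lc.subtract(fa, fb))
        assert len(table) == 43

    def test_fold_sign_matches_delta_sign(self):
        fa, fb = planted_fingerprints(42, {"L01": 2.0, "L09": 0.5}, n_lectins=20)
        table = lc.radar_export(lc.subtract(fa, fb))
        nz = table[table["delta"] != 0]
        assert np.all(np.sign(nz["delta"]) == np.sign(nz["signed_fold_change"]))


GPR_TEXT = (
    "ATF\t1.0\n"
    "4\t10\n"
    '"Type=GenePix Results 3"\n'
    '"DateTime=2020/01/01 10:00:00"\n'
    '"Wavelengths=635"\n'
    '"ImageFiles=slide.tif"\n'
    '"Block"\t"Column"\t"Row"\t"Name"\t"ID"\t"F635 Median"\t"B635 Median"\n'
    '1\t1\t1\t"ACA"\t"lec1"\t5123\t101\n'
    '1\t2\t1\t"ACA"\t"lec1"\t5240\t99\n'
    '1\t3\t1\t"RCA120"\t"lec2"\t801\t95\n'
    '1\t4\t1\t""\t"empty"\t55\t50\n'
)


class TestGprReader:
    def test_minimal_dialect(self):
        table = lc.read_gpr(_io.StringIO(GPR_TEXT), condition="sw48", replicate_id="r1")
        assert list(table.columns) == list(lc.SPOT_COLUMNS)
        assert len(table) == 3  # empty-name row dropped
        aca = table[table["lectin"] == "ACA"]
        assert list(aca["intensity"]) == [5123, 5240]
        assert list(aca["spot_index"]) == [0, 1]
        assert set(table["condition"]) == {"sw48"}

    def test_no_header_rejected(self):
        with pytest.raises(ValueError):
            lc.read_gpr(_io.StringIO("ATF\t1.0\njunk\n"), "c", "r")

    def test_feeds_aggregate(self):
        t1 = lc.read_gpr(_io.StringIO(GPR_TEXT), condition="sw48", replicate_id="r1")
        t2 = lc.read_gpr(_io.StringIO(GPR_TEXT), condition="sw48", replicate_id="r2")
        fps = lc.aggregate(pd.concat([t1, t2], ignore_index=True))
        assert fps["sw48"].table["n"].tolist() == [2, 2]
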