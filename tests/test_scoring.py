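"""Outlier exclusion, control normalization, z-scores, ratios, assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from nephroscreen import scoring
from nephroscreen.morphometry import PARAM_NAMES
from nephroscreen.plate_io import (
    CATEGORIES,
    AnnotationRecord,
    GrossMorphologyRecord,
    WellAddress,
)
from nephroscreen.scoring import (
    AbnormalityRule,
    NormalizationError,
    category_ratios,
    control_fold_change,
    fc_col,
    filter_outliers,
    flag_abnormal,
    gross_col,
    gross_ratios,
    ratio_col,
    z_col,
    zscore_features,
)

from conftest import make_result_frame


class TestFilterOutliers:
    def test_zero_variance_keeps_everything(self):
        res = filter_outliers([10, 10, 10, 10, 10])
        assert res.keep_mask.all()
        assert not res.warned

    def test_nine_zeros_one_hundred(self):
        """m = 10, sample SD = √1000 ≈ 31.62 → only the 100 exceeds 2·SD."""
        values = [0.0] * 9 + [100.0]
        res = filter_outliers(values)
        assert res.keep_mask.sum() == 9
        assert not res.keep_mask[-1]
        np.testing.assert_array_equal(res.kept, np.zeros(9))

    def test_short_series_unfiltered_with_warning_flag(self):
        res = filter_outliers([1.0, 100.0])
        assert res.keep_mask.all()
        assert res.warned

    def test_gaussian_exclusion_rate_matches_normal_tail(self):
        """2·SD filter on 100,000 normal draws excludes ≈ 2(1−Φ(2)) = 4.55%."""
        rng = np.random.default_rng(12345)
        res = filter_outliers(rng.standard_normal(100_000))
        frac = 1.0 - res.keep_mask.mean()
        assert frac == pytest.approx(0.0455, abs=0.004)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers([])

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_outliers([1, 2, 3], k=0)


def _feature_frame(rows):
    """rows: (treatment, day, is_control, value) — value fills all 10 params."""
    records = []
    for i, (treatment, day, is_control, value) in enumerate(rows):
        rec = {
            "plate": "P01",
            "well": f"A{i + 1:02d}",
            "day": day,
            "treatment": treatment,
            "embryo": 1,
            "is_control": is_control,
            **{p: float(value) for p in PARAM_NAMES},
        }
        records.append(rec)
    return pd.DataFrame(records)


class TestControlFoldChange:
    def test_value_equal_to_control_mean_gives_unit_fold_change(self):
        frame = _feature_frame(
            [("DMSO_P01", "d1", True, 2.0)] * 4 + [("C1", "d1", False, 2.0)] * 3
        )
        _, pt, _ = control_fold_change(frame)
        row = pt.set_index("treatment").loc["C1"]
        assert row[fc_col("glomSep")] == pytest.approx(1.0)

    def test_simple_ratio(self):
        frame = _feature_frame(
            [("DMSO_P01", "d1", True, 2.0)] * 4 + [("C1", "d1", False, 3.0)] * 3
        )
        _, pt, _ = control_fold_change(frame)
        assert pt.set_index("treatment").loc["C1", fc_col("tubDist")] == pytest.approx(
            1.5
        )

    def test_controls_average_to_one_per_day_exactly(self, small_screen):
        pe = small_screen.per_embryo
        ctrl = pe[pe["is_control"]]
        for day, grp in ctrl.groupby("day"):
            for p in PARAM_NAMES:
                mean = grp[fc_col(p)].mean()
                assert mean == pytest.approx(1.0, abs=1e-12), (day, p)

    def test_missing_day_controls_rejected(self):
        frame = _feature_frame(
            [("DMSO_P01", "d1", True, 2.0)] * 3 + [("C1", "d2", False, 3.0)] * 3
        )
        with pytest.raises(NormalizationError, match="d2"):
            control_fold_change(frame)

    def test_row_order_permutation_invariance(self, small_screen):
        features = small_screen.tables.features
        shuffled = features.sample(frac=1.0, random_state=5).reset_index(drop=True)
        _, pt_a, _ = control_fold_change(features)
        _, pt_b, _ = control_fold_change(shuffled)
        pd.testing.assert_frame_equal(
            pt_a.sort_values("treatment").reset_index(drop=True),
            pt_b.sort_values("treatment").reset_index(drop=True),
        )


class TestZScores:
    def test_three_point_column(self):
        df = pd.DataFrame({"treatment": ["a", "b", "c"], "fc_glomSep": [1, 2, 3.0]})
        out = zscore_features(df)
        np.testing.assert_allclose(out[z_col("glomSep")], [-1.0, 0.0, 1.0])

    def test_constant_column_zeroed_with_warning(self):
        df = pd.DataFrame({"treatment": list("abc"), "fc_glomSep": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_features(df)
        np.testing.assert_array_equal(out[z_col("glomSep")], 0.0)

    def test_single_row_rejected(self):
        df = pd.DataFrame({"treatment": ["a"], "fc_glomSep": [1.0]})
        with pytest.raises(ValueError, match="two treatments"):
            zscore_features(df)

    def test_columns_standardized_to_machine_precision(self, small_screen):
        z = zscore_features(small_screen.per_treatment)
        for p in PARAM_NAMES:
            col = z[z_col(p)].dropna()
            assert abs(col.mean()) < 1e-9
            assert abs(col.std(ddof=1) - 1.0) < 1e-9


def _well(i: int) -> WellAddress:
    return WellAddress(plate="P01", row="A", column=i)


class TestCategoryRatios:
    def test_simple_fraction(self):
        annotations = [
            AnnotationRecord(
                well=_well(i + 1),
                embryo=1,
                categories=frozenset(
                    {"glom_malform"} if i < 3 else {"normal_kidney"}
                ),
            )
            for i in range(10)
        ]
        tmap = {("P01", f"A{i + 1:02d}"): "C1" for i in range(10)}
        out = category_ratios(annotations, tmap).set_index("treatment")
        assert out.loc["C1", ratio_col("glom_malform")] == pytest.approx(0.3)
        assert out.loc["C1", ratio_col("normal_kidney")] == pytest.approx(0.7)

    def test_all_normal(self):
        annotations = [
            AnnotationRecord(
                well=_well(i + 1), embryo=1, categories=frozenset({"normal_kidney"})
            )
            for i in range(5)
        ]
        tmap = {("P01", f"A{i + 1:02d}"): "C1" for i in range(5)}
        out = category_ratios(annotations, tmap).set_index("treatment")
        assert out.loc["C1", ratio_col("normal_kidney")] == 1.0
        others = [ratio_col(c) for c in CATEGORIES if c != "normal_kidney"]
        assert (out.loc["C1", others] == 0.0).all()

    def test_multi_tag_embryos_count_in_each_ratio(self):
        annotations = [
            AnnotationRecord(
                well=_well(1),
                embryo=1,
                categories=frozenset({"glomsep_maj", "rpa_min"}),
            ),
            AnnotationRecord(
                well=_well(2), embryo=1, categories=frozenset({"empty"})
            ),
        ]
        tmap = {("P01", "A01"): "C1", ("P01", "A02"): "C1"}
        out = category_ratios(annotations, tmap).set_index("treatment")
        assert out.loc["C1", ratio_col("glomsep_maj")] == 0.5
        assert out.loc["C1", ratio_col("rpa_min")] == 0.5
        assert out.loc["C1", ratio_col("empty")] == 0.5
        ratio_sum = out.loc["C1", [ratio_col(c) for c in CATEGORIES]].sum()
        assert ratio_sum == pytest.approx(1.5)  # multi-tags push the sum past 1

    def test_no_annotations_rejected(self):
        with pytest.raises(ValueError, match="no annotated"):
            category_ratios([], {})


class TestGrossRatios:
    def test_fraction_of_exposed(self):
        rec = GrossMorphologyRecord(treatment="C1", edema_mild=5, total_exposed=20)
        assert gross_ratios(rec)[gross_col("edema_mild")] == 0.25

    def test_total_mortality(self):
        rec = GrossMorphologyRecord(treatment="C1", mortality=20, total_exposed=20)
        out = gross_ratios(rec)
        assert out["mortality"] == 1.0
        assert out[gross_col("yolk_necrosis")] == 0.0


class TestAssembly:
    def test_26_scored_parameters(self, small_screen):
        assert len(small_screen.table.scored_parameters) == 26
        assert set(small_screen.table.scored_parameters) <= set(
            small_screen.table.frame.columns
        )

    def test_one_record_per_treatment(self, small_screen):
        frame = small_screen.table.frame
        features = small_screen.tables.features
        expected = set(features["treatment"])
        assert not frame["treatment"].duplicated().any()
        assert expected <= set(frame["treatment"])

    def test_all_empty_treatment_flagged_missing(self, small_screen):
        """A treatment whose embryos all died keeps qualitative fields only."""
        import io

        from nephroscreen import plate_io as pio
        from nephroscreen import synthetic_data as synth

        scr = small_screen
        dead_wells = [
            AnnotationRecord(
                well=WellAddress(plate="PX", row="A", column=i + 1),
                embryo=1,
                categories=frozenset({"empty"}),
            )
            for i in range(8)
        ]
        tmap = synth.treatment_map(scr.config)
        tmap.update({("PX", f"A{i + 1:02d}"): "C9999" for i in range(8)})
        compounds = scr.design.compounds.copy()
        compounds.loc[len(compounds)] = ["C9999", "dead compound", ""]
        comp_buf = io.StringIO(compounds.to_csv(index=False))
        atc_buf = io.StringIO(scr.design.atc.to_csv(index=False))
        library = pio.load_library(comp_buf, atc_buf)
        table = scoring.assemble_results(
            scr.per_treatment,
            list(scr.tables.annotations) + dead_wells,
            scr.tables.gross,
            library,
            tmap,
        )
        row = table.frame.set_index("treatment").loc["C9999"]
        assert bool(row["quantitative_missing"])
        assert row[ratio_col("empty")] == 1.0
        assert np.isnan(row[fc_col("glomSep")])

    def test_unknown_compound_rejected_unless_allowed(self, small_screen):
        from nephroscreen import synthetic_data as synth

        scr = small_screen
        tmap = synth.treatment_map(scr.config)
        with pytest.raises(ValueError, match="absent from compound library"):
            scoring.assemble_results(
                scr.per_treatment,
                scr.tables.annotations,
                scr.tables.gross,
                [],  # empty library
                tmap,
            )
        table = scoring.assemble_results(
            scr.per_treatment,
            scr.tables.annotations,
            scr.tables.gross,
            [],
            tmap,
            allow_unknown_compounds=True,
        )
        labels = table.frame.loc[~table.frame["is_control"], "compound_name"]
        assert (labels == "unknown compound").all()


class TestAbnormalityFlag:
    def test_fully_normal_profile_not_flagged(self):
        table = make_result_frame([{}])
        flags = flag_abnormal(table)
        assert not flags["abnormal"].iloc[0]

    def test_category_ratio_clause(self):
        table = make_result_frame(
            [{ratio_col("glomsep_maj"): 0.6, ratio_col("normal_kidney"): 0.4}]
        )
        flags = flag_abnormal(table)
        assert flags["abnormal"].iloc[0]
        assert "glomsep_maj" in flags["fired_rules"].iloc[0]

    def test_zscore_clause(self):
        table = make_result_frame([{z_col("tubDist"): -2.5}])
        flags = flag_abnormal(table)
        assert flags["abnormal"].iloc[0]
        assert "z_tubDist" in flags["fired_rules"].iloc[0]

    def test_clauses_can_be_disabled(self):
        table = make_result_frame([{z_col("tubDist"): -2.5}])
        rule = AbnormalityRule(min_abs_z=None)
        assert not flag_abnormal(table, rule)["abnormal"].iloc[0]

    def test_recovers_planted_abnormal_fraction(self, reference_screen):
        """Flagged fraction tracks the planted 10% of strong compounds."""
        scr = reference_screen
        truth = scr.tables.ground_truth.set_index("treatment")["planted_abnormal"]
        merged = scr.flags.set_index("treatment").join(truth)
        compounds = merged[~merged.index.str.startswith("DMSO_")]
        planted = compounds["planted_abnormal"].mean()
        flagged = compounds["abnormal"].mean()
        assert abs(flagged - planted) < 0.03
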