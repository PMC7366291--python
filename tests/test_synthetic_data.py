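"""The synthetic screen generator against its own stated generative model."""

import math

import numpy as np
import pandas as pd
import pytest

from nephroscreen import scoring
from nephroscreen.image_processing import detect_roi_center, max_project
from nephroscreen.morphometry import PARAM_NAMES, compute_features
from nephroscreen.synthetic_data import (
    DEFAULT_BASELINE,
    ConfigurationError,
    RenderBoundsError,
    ScreenSimConfig,
    assign_categories,
    design_screen,
    generate_plate,
    landmarks_from_params,
    render_embryo_stack,
    sample_embryo_params,
    simulate_measurement_table,
    simulate_screen_tables,
    treatment_map,
)

UNIT = tuple([1.0] * 10)


def _config(n_compounds=1, **kw) -> ScreenSimConfig:
    vectors = kw.pop(
        "effect_vectors",
        {f"C{i + 1:04d}": UNIT for i in range(n_compounds)},
    )
    defaults = dict(
        n_compounds=n_compounds,
        effect_vectors=vectors,
        image_size=(400, 400),
        seed=123,
    )
    defaults.update(kw)
    return ScreenSimConfig(**defaults)


def baseline_array() -> np.ndarray:
    return np.array([DEFAULT_BASELINE[n] for n in PARAM_NAMES])


class TestSampling:
    def test_zero_cv_control_equals_baseline_exactly(self):
        cfg = _config(biological_cv=0.0)
        rng = np.random.default_rng(0)
        params = sample_embryo_params(cfg, "C0001", rng)
        np.testing.assert_array_equal(params, baseline_array())

    def test_zero_cv_effect_scales_deterministically(self):
        # doubled tubular distance, everything else untouched
        effect = list(UNIT)
        effect[PARAM_NAMES.index("tubDist")] = 2.0
        cfg = _config(effect_vectors={"C0001": tuple(effect)}, biological_cv=0.0)
        params = sample_embryo_params(cfg, "C0001", np.random.default_rng(0))
        expected = baseline_array()
        expected[PARAM_NAMES.index("tubDist")] *= 2.0
        np.testing.assert_array_equal(params, expected)

    def test_unknown_treatment_is_a_configuration_error(self):
        cfg = _config()
        with pytest.raises(ConfigurationError, match="C9999"):
            sample_embryo_params(cfg, "C9999", np.random.default_rng(0))

    def test_lognormal_mean_matches_target(self):
        """10,000 draws at CV 0.1: sample mean within 1% of baseline × effect."""
        effect = list(UNIT)
        i = PARAM_NAMES.index("glomSep")
        effect[i] = 1.5
        cfg = _config(effect_vectors={"C0001": tuple(effect)}, biological_cv=0.1)
        rng = np.random.default_rng(42)
        draws = np.array(
            [sample_embryo_params(cfg, "C0001", rng)[i] for i in [i] * 10_000]
        )
        target = DEFAULT_BASELINE["glomSep"] * 1.5
        assert abs(draws.mean() / target - 1.0) < 0.01

    def test_bilateral_sides_are_correlated(self):
        cfg = _config(biological_cv=0.2, bilateral_correlation=0.5)
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_embryo_params(cfg, "C0001", rng) for _ in range(4000)]
        )
        iL, iR = PARAM_NAMES.index("glomWidthL"), PARAM_NAMES.index("glomWidthR")
        r = np.corrcoef(np.log(draws[:, iL]), np.log(draws[:, iR]))[0, 1]
        assert r == pytest.approx(0.5, abs=0.06)
        iT = PARAM_NAMES.index("tubDist")
        r_unrelated = np.corrcoef(np.log(draws[:, iL]), np.log(draws[:, iT]))[0, 1]
        assert abs(r_unrelated) < 0.06

    def test_angles_capped_at_180(self):
        effect = list(UNIT)
        effect[PARAM_NAMES.index("angleL")] = 1.6  # 120° × 1.6 = 192° → capped
        cfg = _config(effect_vectors={"C0001": tuple(effect)}, biological_cv=0.0)
        params = sample_embryo_params(cfg, "C0001", np.random.default_rng(0))
        assert params[PARAM_NAMES.index("angleL")] == 180.0


class TestCategories:
    @pytest.mark.parametrize(
        "param, fold, expected",
        [
            ("glomSep", 1.25, "glomsep_min"),
            ("glomSep", 1.40, "glomsep_mod"),
            ("glomSep", 1.55, "glomsep_maj"),
            ("glomWidthL", 1.40, "glom_malform"),
            ("glomHeightR", 1 / 1.40, "glom_malform"),
        ],
    )
    def test_fold_thresholds(self, param, fold, expected):
        cfg = _config()
        params = baseline_array()
        params[PARAM_NAMES.index(param)] *= fold
        assert assign_categories(cfg, params) == frozenset({expected})

    @pytest.mark.parametrize(
        "fold, expected",
        [(1 / 1.25, "rpa_min"), (1 / 1.4, "rpa_mod"), (1 / 1.6, "rpa_maj")],
    )
    def test_reduced_angle_thresholds(self, fold, expected):
        cfg = _config()
        params = baseline_array()
        params[PARAM_NAMES.index("angleL")] *= fold
        assert assign_categories(cfg, params) == frozenset({expected})

    def test_baseline_embryo_is_normal(self):
        cfg = _config()
        assert assign_categories(cfg, baseline_array()) == frozenset(
            {"normal_kidney"}
        )


class TestLandmarksAndRendering:
    def test_morphometry_inverts_landmark_construction(self):
        """Features computed from constructed landmarks recover the parameters."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            params = baseline_array() * rng.uniform(0.7, 1.4, size=10)
            params[:2] = np.clip(params[:2], 20.0, 179.0)
            lms = landmarks_from_params(params, center=(500.0, 500.0))
            feats = compute_features(lms).as_array()
            np.testing.assert_allclose(feats, params, rtol=1e-9, atol=1e-9)

    def test_landmarks_lie_on_rendered_foreground(self):
        """Noise off, PSF 0: every landmark pixel is above background."""
        cfg = _config(
            biological_cv=0.0,
            read_noise_sd=0.0,
            shot_noise=False,
            psf_sigma=0.0,
            defocus_sigma_per_slice=0.0,
        )
        params = sample_embryo_params(cfg, "C0001", np.random.default_rng(0))
        stack, lms = render_embryo_stack(
            params, cfg, np.random.default_rng(1), center=(200.0, 200.0)
        )
        focal = stack.pixels[cfg.n_slices // 2]
        for name, (x, y) in lms.points.items():
            assert focal[round(y), round(x)] > cfg.background, name

    def test_default_stack_has_ten_slices_at_15um(self):
        cfg = _config()
        params = sample_embryo_params(cfg, "C0001", np.random.default_rng(0))
        stack, _ = render_embryo_stack(params, cfg, np.random.default_rng(1))
        assert stack.n_slices == 10
        assert stack.slice_spacing_um == 15.0

    def test_roundtrip_through_rendered_landmarks(self):
        cfg = _config(biological_cv=0.0)
        params = sample_embryo_params(cfg, "C0001", np.random.default_rng(0))
        _, lms = render_embryo_stack(params, cfg, np.random.default_rng(2))
        feats = compute_features(lms).as_array()
        np.testing.assert_allclose(feats, params, rtol=1e-9)

    def test_geometry_exceeding_frame_rejected(self):
        cfg = _config()
        params = baseline_array()
        params[PARAM_NAMES.index("tubDist")] = 900.0  # wider than the 400-px frame
        with pytest.raises(RenderBoundsError):
            render_embryo_stack(params, cfg, np.random.default_rng(0))

    def test_detected_roi_lands_near_true_center(self):
        cfg = _config(biological_cv=0.0)
        params = sample_embryo_params(cfg, "C0001", np.random.default_rng(0))
        stack, lms = render_embryo_stack(
            params, cfg, np.random.default_rng(3), center=(230.0, 180.0)
        )
        cx, cy = detect_roi_center(max_project(stack))
        coords = lms.as_array()
        gx, gy = coords[:, 0].mean(), coords[:, 1].mean()
        assert math.hypot(cx - gx, cy - gy) < 25.0


class TestPlateGeneration:
    def test_no_lethality_fills_every_well(self):
        cfg = _config(n_compounds=7, embryos_per_treatment=12, lethality_prob=0.0)
        plate = generate_plate(cfg, 0, render_images=False)
        assert len(plate.ground_truth) == cfg.wells_per_plate == 96
        assert not plate.ground_truth["empty"].any()

    def test_full_lethality_gives_only_empty_annotations(self):
        cfg = _config(n_compounds=7, lethality_prob=1.0)
        plate = generate_plate(cfg, 0, render_images=False)
        assert plate.ground_truth["empty"].all()
        assert all(r.categories == frozenset({"empty"}) for r in plate.annotations)
        assert len(plate.stacks) == 0

    def test_empty_fraction_matches_binomial_rate(self):
        """~10,000 wells at lethality 0.2: empty fraction within 0.01 of 0.2."""
        cfg = _config(
            n_compounds=700, embryos_per_treatment=12, lethality_prob=0.2, seed=9
        )
        tables = simulate_screen_tables(cfg)
        n_wells = sum(
            1 for r in tables.annotations
        )
        n_empty = sum(
            1 for r in tables.annotations if "empty" in r.categories
        )
        assert n_wells >= 9600
        assert abs(n_empty / n_wells - 0.2) < 0.01

    def test_regenerating_one_plate_is_deterministic(self):
        cfg = _config(n_compounds=14, seed=31)
        a = generate_plate(cfg, 1, render_images=False)
        b = generate_plate(cfg, 1, render_images=False)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        assert a.annotations == b.annotations
        assert a.gross == b.gross

    def test_rendered_plate_is_bit_identical_across_runs(self):
        cfg = _config(n_compounds=1, embryos_per_treatment=1, seed=4,
                      lethality_prob=0.0)
        a = generate_plate(cfg, 0)
        b = generate_plate(cfg, 0)
        assert set(a.stacks) == set(b.stacks)
        for well in a.stacks:
            np.testing.assert_array_equal(a.stacks[well].pixels, b.stacks[well].pixels)

    def test_control_row_is_dmso(self):
        cfg = _config(n_compounds=7)
        layout = cfg.plate_layout(0)
        assert layout["H"] == "DMSO_P01"
        assert (cfg.effect_for("DMSO_P01") == 1.0).all()


class TestMeasurementTable:
    def test_control_only_zero_cv_gives_unit_fold_changes(self):
        cfg = _config(n_compounds=7, biological_cv=0.0, lethality_prob=0.0)
        features = simulate_measurement_table(cfg)
        _, per_treatment, _ = scoring.control_fold_change(features)
        fc_cols = [scoring.fc_col(p) for p in PARAM_NAMES]
        controls_and_nulls = per_treatment[fc_cols].to_numpy()
        np.testing.assert_allclose(controls_and_nulls, 1.0, rtol=1e-12)

    def test_shape_contract_200_compounds(self, reference_screen):
        """200 compounds × 8 embryos yields a 200-row × 10-feature aggregate."""
        pt = reference_screen.per_treatment
        compounds = pt[~pt["is_control"]]
        assert len(compounds) == 200
        fc_cols = [scoring.fc_col(p) for p in PARAM_NAMES]
        assert compounds[fc_cols].shape == (200, 10)

    def test_planted_effect_recovered_within_two_se(self, reference_screen):
        """Mean fold change over planted 1.5× shifts lands within 2 SE of 1.5.

        Any single treatment's fold change also carries its plate-day's
        control-mean noise, so the check averages the fc/effect ratio over
        all compounds planted with an increase on glomerular separation.
        """
        scr = reference_screen
        truth = scr.tables.ground_truth.set_index("treatment")
        pt = scr.per_treatment.set_index("treatment")
        eff = truth["effect_glomSep"]
        planted = eff[(eff > 1.0) & ~truth["is_control"]].index
        assert len(planted) >= 5
        ratios = (pt.loc[planted, scoring.fc_col("glomSep")] / eff.loc[planted])
        se = ratios.std(ddof=1) / math.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 2 * se + 0.005

    def test_determinism_of_tables(self):
        cfg = _config(n_compounds=14, seed=77)
        t1 = simulate_screen_tables(cfg)
        t2 = simulate_screen_tables(cfg)
        pd.testing.assert_frame_equal(t1.features, t2.features)
        assert t1.annotations == t2.annotations

    def test_treatment_map_covers_all_wells(self):
        cfg = _config(n_compounds=14)
        tmap = treatment_map(cfg)
        assert len(tmap) == 2 * 8 * cfg.embryos_per_treatment
        assert tmap[("P01", "H01")] == "DMSO_P01"


class TestConfigValidation:
    def test_effect_vector_length_checked(self):
        with pytest.raises(ConfigurationError, match="length"):
            _config(effect_vectors={"C0001": (1.0, 2.0)})

    def test_probabilities_bounded(self):
        with pytest.raises(ConfigurationError, match="probability"):
            _config(lethality_prob=1.5)

    def test_negative_baseline_rejected(self):
        bad = dict(DEFAULT_BASELINE)
        bad["glomSep"] = -1.0
        with pytest.raises(ConfigurationError, match="glomSep"):
            _config(baseline_geometry=bad)

    def test_yaml_round_trip(self, tmp_path):
        cfg = _config(n_compounds=3, biological_cv=0.05)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        loaded = ScreenSimConfig.from_yaml(path)
        assert loaded == cfg
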