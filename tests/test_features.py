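"""Spectral indices, GLCM construction and Haralick statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopylai import features, synthdata
from canopylai.features import (
    SPECTRAL_NAMES,
    FeatureConfig,
    compute_glcm,
    compute_spectral_features,
    compute_texture_features,
    extract_patch_features,
    texture_feature_names,
    texture_sensitivity_sweep,
    window_footprint,
)
from canopylai.types import RGBPatch


def _pixel(r, g, b):
    return RGBPatch(np.array([[[r, g, b]]], dtype=float))


class TestSpectral:
    def test_uniform_gray_pixel(self):
        v = compute_spectral_features(_pixel(100, 100, 100)).values
        assert v["RCC"] == pytest.approx(1 / 3)
        assert v["GCC"] == pytest.approx(1 / 3)
        assert v["BCC"] == pytest.approx(1 / 3)
        assert v["GRVI"] == 0.0
        assert v["EXG"] == pytest.approx(0.0)
        assert v["GRRI"] == 1.0
        assert v["MRGB"] == 100.0
        assert v["SDRG"] == 0.0

    def test_pure_green_pixel(self):
        v = compute_spectral_features(_pixel(0, 255, 0)).values
        assert v["GCC"] == 1.0
        assert v["EXG"] == pytest.approx(2.0)
        assert v["GRVI"] == 1.0
        assert v["WI"] == pytest.approx(-1.0)

    def test_black_pixel_constant_and_division_policy(self):
        sv = compute_spectral_features(_pixel(0, 0, 0))
        assert sv.values["CIVE"] == pytest.approx(18.78745)
        # chromatic coordinates hit 0/0 and take the policy value
        assert sv.values["RCC"] == 0.0
        assert sv.degenerate_counts["RCC"] == 1

    def test_vector_has_exactly_26_entries(self):
        sv = compute_spectral_features(_pixel(10, 20, 30))
        assert list(sv.values) == list(SPECTRAL_NAMES)
        assert len(sv.values) == 26

    def test_chromatic_coordinates_sum_to_one(self, rng):
        patch = RGBPatch(rng.random((5, 5, 3)) + 0.1)
        v = compute_spectral_features(patch).values
        assert v["RCC"] + v["GCC"] + v["BCC"] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        r=st.floats(1.0, 250.0),
        g=st.floats(1.0, 250.0),
        b=st.floats(1.0, 250.0),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_invariance_of_ratio_indices(self, r, g, b, k):
        """Chromatic/ratio indices ignore global gain; sums scale linearly."""
        v1 = compute_spectral_features(_pixel(r, g, b)).values
        v2 = compute_spectral_features(_pixel(k * r, k * g, k * b)).values
        for name in ("RCC", "GCC", "BCC", "GRRI", "GBRI", "RBRI", "GRVI",
                     "NDI", "IKAW", "GLI", "VARI", "EXR", "EXG", "EXB", "CI"):
            assert v2[name] == pytest.approx(v1[name], rel=1e-9, abs=1e-9)
        for name in ("MRGB", "SDGB", "SDRB", "SDRG"):
            assert v2[name] == pytest.approx(k * v1[name], rel=1e-9)

    def test_aggregation_modes_agree_on_constant_patch(self):
        patch = RGBPatch(np.tile([[0.2, 0.5, 0.1]], (4, 4, 1)))
        a = compute_spectral_features(patch, "mean-then-index").values
        b = compute_spectral_features(patch, "index-then-mean").values
        for name in SPECTRAL_NAMES:
            assert a[name] == pytest.approx(b[name])


def _glcm_bruteforce(window, levels, displacement, value_range=None):
    """Independent oracle: explicit pair enumeration with symmetric counts."""
    q = features.quantize(np.asarray(window, float), levels, value_range)
    dr, dc = displacement
    counts = np.zeros((levels, levels))
    h, w = q.shape
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w:
                counts[q[i, j], q[i2, j2]] += 1
                counts[q[i2, j2], q[i, j]] += 1
    return counts / counts.sum()


class TestGLCM:
    def test_hand_counted_two_by_two(self):
        g = compute_glcm(
            np.array([[0.0, 0.0], [1.0, 1.0]]), levels=2, displacement=(0, 1)
        )
        np.testing.assert_allclose(g.p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_window_single_occupied_cell(self):
        g = compute_glcm(np.full((4, 4), 7.0), levels=8, displacement=(1, 1))
        assert g.p[0, 0] == 1.0
        assert g.p.sum() == 1.0

    def test_probabilities_normalized_and_symmetric(self, rng):
        g = compute_glcm(rng.random((9, 9)), levels=8, displacement=(2, 2))
        assert g.p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(g.p, g.p.T)

    @pytest.mark.parametrize("displacement", [(0, 1), (1, 0), (1, 1), (2, 2), (1, -1)])
    def test_matches_bruteforce_oracle_exactly(self, rng, displacement):
        for _ in range(5):
            h, w = rng.integers(3, 5, size=2)
            window = rng.random((h, w))
            g = compute_glcm(window, levels=4, displacement=displacement)
            oracle = _glcm_bruteforce(window, 4, displacement)
            np.testing.assert_array_equal(g.p, oracle)

    def test_window_smaller_than_displacement_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((2, 2)), levels=2, displacement=(2, 2))

    def test_contrast_invariant_to_constant_shift(self, rng):
        window = rng.random((8, 8))
        t1 = compute_texture_features(compute_glcm(window, 8, (1, 1)))
        t2 = compute_texture_features(compute_glcm(window + 5.0, 8, (1, 1)))
        for stat in ("CON", "DIS", "HOM"):
            assert t1.values[stat] == pytest.approx(t2.values[stat], abs=1e-12)


class TestTextureStats:
    def test_diagonal_half_half_distribution(self):
        g = compute_glcm(
            np.array([[0.0, 0.0], [1.0, 1.0]]), levels=2, displacement=(0, 1)
        )
        v = compute_texture_features(g).values
        assert v["CON"] == 0.0
        assert v["SEC"] == 0.5
        assert v["ENT"] == pytest.approx(np.log(2))
        assert v["HOM"] == 1.0
        assert v["DIS"] == 0.0

    def test_degenerate_single_entry(self):
        g = compute_glcm(np.full((3, 3), 2.0), levels=4, displacement=(1, 0))
        v = compute_texture_features(g).values
        assert v["ENT"] == 0.0
        assert v["SEC"] == 1.0
        assert v["COR"] == 0.0  # zero marginal variance policy

    def test_uniform_distribution_closed_form(self):
        from canopylai.features import GLCMatrix

        p = np.full((2, 2), 0.25)
        v = compute_texture_features(
            GLCMatrix(p=p, levels=2, window_shape=(2, 2), displacement=(0, 1))
        ).values
        assert v["ENT"] == pytest.approx(np.log(4))
        assert v["SEC"] == pytest.approx(0.25)

    def test_correlation_bounds_on_random_windows(self, rng):
        for _ in range(10):
            g = compute_glcm(rng.random((8, 8)), levels=6, displacement=(1, 1))
            v = compute_texture_features(g).values
            assert -1.0 <= v["COR"] <= 1.0
            assert 0.0 < v["HOM"] <= 1.0
            assert 0.0 < v["SEC"] <= 1.0
            assert v["ENT"] >= 0.0


class TestExtraction:
    def test_full_candidate_set_has_50_values(self, rng):
        patch = RGBPatch(rng.random((12, 12, 3)))
        vec = extract_patch_features(patch)
        assert len(vec) == 50
        assert list(vec.index[:26]) == list(SPECTRAL_NAMES)

    def test_configured_subset_preserves_order_and_length(self, rng):
        names = tuple(["MRGB", "EXG", "CON_G", "MEA_R"] + list(SPECTRAL_NAMES[:14]))
        vec = extract_patch_features(
            RGBPatch(rng.random((12, 12, 3))), FeatureConfig(feature_subset=names)
        )
        assert len(vec) == 18
        assert list(vec.index) == list(names)

    def test_unknown_feature_name_rejected(self):
        with pytest.raises(KeyError):
            FeatureConfig(feature_subset=("MRGB", "NOPE"))

    def test_patch_smaller_than_window_uses_single_window(self, rng):
        patch = RGBPatch(rng.random((5, 5, 3)))
        vec = extract_patch_features(patch, FeatureConfig(glcm_window=9))
        assert np.isfinite(vec).all()


class TestFootprint:
    @pytest.mark.parametrize(
        "px,res,expected", [(9, 0.83, 7.47), (2, 0.83, 1.66), (1, 1.0, 1.0)]
    )
    def test_physical_footprint(self, px, res, expected):
        assert window_footprint(px, res) == pytest.approx(expected)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            window_footprint(0, 0.83)
        with pytest.raises(ValueError):
            window_footprint(9, -1.0)


@pytest.fixture(scope="module")
def sweep_samples():
    cfg = synthdata.SceneConfig(
        n_points=40, resolution_cm=10.0, patch_size=24, seed=21,
        gain_range=(1.0, 1.0), bias_range=(0.0, 0.0), texture_noise=0.12,
    )
    return synthdata.generate_time_series_dataset(cfg)


class TestSensitivitySweep:
    def test_default_grid_yields_15_settings(self, sweep_samples):
        table = texture_sensitivity_sweep(sweep_samples)
        assert len(table) == 5 * 3
        assert set(table["window"]) == {3, 5, 7, 9, 11}
        assert set(table["displacement"]) == {1, 2, 3}

    def test_single_setting_single_row(self, sweep_samples):
        table = texture_sensitivity_sweep(
            sweep_samples, windows=[9], displacements=[2]
        )
        assert len(table) == 1

    def test_lai_coupled_texture_gives_positive_contrast_correlation(
        self, sweep_samples
    ):
        """Texture amplitude grows with LAI, so CON-LAI r > 0 at every
        setting that admits a co-occurring pair."""
        table = texture_sensitivity_sweep(sweep_samples)
        valid = table[table["window"] > table["displacement"]]
        assert (valid["CON_G"] > 0).all()
        assert (valid["CON_R"] > 0).all()
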