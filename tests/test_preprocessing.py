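"""Calibration, histogram matching, normalization and gap filling."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from canopylai import preprocessing, synthdata
from canopylai.preprocessing import (
    MissingTimestepRejection,
    apply_normalization,
    apply_radiometric_calibration,
    fill_missing_timesteps,
    fit_normalization,
    fit_radiometric_response,
    histogram_match,
)
from canopylai.synthdata import PanelConfig
from canopylai.types import RGBPatch, TemporalSample


def _two_point_panel():
    dn = np.array([[0.0, 0.0, 0.0], [255.0, 255.0, 255.0]])
    refl = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    return SimpleNamespace(dn=dn, reflectance=refl)


class TestResponseCurve:
    def test_linear_interpolation_between_knots(self):
        curve = fit_radiometric_response(_two_point_panel())
        assert curve(127.5, band=0) == pytest.approx(0.5)

    def test_exact_at_all_panel_knots(self):
        panel = synthdata.generate_panel_observations(PanelConfig(gamma=1.0))
        curve = fit_radiometric_response(panel)
        for b in range(3):
            np.testing.assert_allclose(
                curve(panel.dn[:, b], band=b), panel.reflectance[:, b]
            )

    def test_extrapolation_clamps_to_end_reflectances(self):
        curve = fit_radiometric_response(_two_point_panel())
        assert curve(-10.0, band=0) == 0.0
        assert curve(1e4, band=0) == 1.0

    def test_non_monotone_panel_names_band_and_step(self):
        dn = np.array([[0.0] * 3, [10.0] * 3, [5.0] * 3, [20.0] * 3])
        refl = np.linspace(0.1, 0.9, 4)[:, None].repeat(3, axis=1)
        with pytest.raises(ValueError, match="band R at step 2"):
            fit_radiometric_response(SimpleNamespace(dn=dn, reflectance=refl))


class TestCalibration:
    def test_identity_curve_preserves_values(self):
        dn = np.linspace(0.0, 255.0, 48).reshape(4, 4, 3)
        patch = RGBPatch(dn, units="dn")
        curve = fit_radiometric_response(
            SimpleNamespace(
                dn=np.array([[0.0] * 3, [255.0] * 3]),
                reflectance=np.array([[0.0] * 3, [1.0] * 3]),
            )
        )
        out = apply_radiometric_calibration(patch, curve)
        np.testing.assert_allclose(out.values, dn / 255.0)
        assert out.units == "reflectance"

    def test_constant_dn_gives_constant_reflectance(self):
        patch = RGBPatch(np.full((3, 3, 3), 100.0), units="dn")
        curve = fit_radiometric_response(_two_point_panel())
        out = apply_radiometric_calibration(patch, curve)
        assert np.unique(out.values).size == 1

    def test_generator_round_trip_recovers_reflectance(self, clean_config):
        """DN conversion then calibration is exact for noise-free panels."""
        panel = synthdata.generate_panel_observations(PanelConfig(gamma=0.5))
        curve = fit_radiometric_response(panel)
        patch = synthdata.render_lai_patch(4.2, clean_config)
        recovered = apply_radiometric_calibration(
            synthdata.to_dn(patch, panel), curve
        )
        np.testing.assert_allclose(recovered.values, patch.values, atol=1e-6)

    def test_reflectance_input_rejected(self):
        patch = RGBPatch(np.zeros((2, 2, 3)), units="reflectance")
        curve = fit_radiometric_response(_two_point_panel())
        with pytest.raises(ValueError):
            apply_radiometric_calibration(patch, curve)


class TestHistogramMatch:
    def test_self_matching_is_identity(self, rng):
        patch = RGBPatch(rng.random((16, 16, 3)))
        out = histogram_match(patch, patch)
        np.testing.assert_allclose(out.values, patch.values, atol=1e-9)

    def test_gain_bias_distortion_removed(self, rng):
        ref = RGBPatch(rng.random((32, 32, 3)))
        distorted = RGBPatch(ref.values * 1.2 + 5.0)
        matched = histogram_match(distorted, ref)
        for b in range(3):
            assert matched.values[:, :, b].mean() == pytest.approx(
                ref.values[:, :, b].mean(), rel=0.01
            )

    def test_constant_reference_gives_constant_output(self, rng):
        image = RGBPatch(rng.random((8, 8, 3)))
        ref = RGBPatch(np.full((8, 8, 3), 0.4))
        out = histogram_match(image, ref)
        np.testing.assert_allclose(out.values, 0.4)

    def test_idempotence(self, rng):
        image = RGBPatch(rng.random((16, 16, 3)))
        ref = RGBPatch(rng.random((16, 16, 3)) * 0.8 + 0.1)
        once = histogram_match(image, ref)
        twice = histogram_match(once, ref)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


class TestNormalization:
    def test_min_max_scaling(self):
        table = pd.DataFrame(
            {"point_id": [1, 2, 3], "stage": 0, "lai": 4.0, "f": [2.0, 4.0, 6.0]}
        )
        stats = fit_normalization(table)
        out = apply_normalization(table, stats)
        np.testing.assert_allclose(out["f"], [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        table = pd.DataFrame(
            {"point_id": [1, 2], "stage": 0, "lai": 4.0, "f": [5.0, 5.0]}
        )
        out = apply_normalization(table, fit_normalization(table))
        np.testing.assert_allclose(out["f"], [0.0, 0.0])

    def test_out_of_range_test_values_not_clamped(self):
        train = pd.DataFrame(
            {"point_id": [1, 2], "stage": 0, "lai": 4.0, "f": [0.0, 10.0]}
        )
        test = pd.DataFrame({"point_id": [3], "stage": 0, "lai": 4.0, "f": [20.0]})
        out = apply_normalization(test, fit_normalization(train))
        assert out["f"].iloc[0] == pytest.approx(2.0)

    def test_unknown_feature_rejected(self):
        train = pd.DataFrame({"point_id": [1, 2], "stage": 0, "lai": 4.0, "f": [0, 1]})
        test = pd.DataFrame({"point_id": [1], "stage": 0, "lai": 4.0, "g": [1.0]})
        with pytest.raises(KeyError):
            apply_normalization(test, fit_normalization(train))

    def test_fit_apply_gives_unit_range_per_column(self, rng):
        table = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        table["point_id"] = range(10)
        table["stage"] = 0
        table["lai"] = 4.0
        out = apply_normalization(table, fit_normalization(table))
        for c in "abcd":
            assert out[c].min() == pytest.approx(0.0)
            assert out[c].max() == pytest.approx(1.0)


def _sample_with(patches):
    return TemporalSample(point_id=0, patches=patches, label=4.0)


class TestMissingTimesteps:
    def _patch(self, value):
        return RGBPatch(np.full((4, 4, 3), float(value)))

    def test_interior_gap_filled_with_neighbour_mean(self):
        out = fill_missing_timesteps(
            _sample_with([self._patch(1.0), None, self._patch(3.0)])
        )
        np.testing.assert_allclose(out.patches[1].values, 2.0)

    def test_edge_gap_takes_nearest_stage(self):
        out = fill_missing_timesteps(
            _sample_with([None, self._patch(2.0), self._patch(3.0)])
        )
        np.testing.assert_allclose(out.patches[0].values, 2.0)
        out = fill_missing_timesteps(
            _sample_with([self._patch(1.0), self._patch(2.0), None])
        )
        np.testing.assert_allclose(out.patches[2].values, 2.0)

    def test_two_missing_stages_rejected_with_reason(self):
        out = fill_missing_timesteps(_sample_with([None, None, self._patch(3.0)]))
        assert isinstance(out, MissingTimestepRejection)
        assert "2 missing" in out.reason

    def test_complete_sample_returned_unchanged(self):
        sample = _sample_with([self._patch(v) for v in (1, 2, 3)])
        assert fill_missing_timesteps(sample) is sample

    def test_fill_all_partitions_dataset(self):
        samples = [
            _sample_with([self._patch(1), None, self._patch(3)]),
            _sample_with([None, None, self._patch(3)]),
        ]
        kept, rejected = preprocessing.fill_all(samples)
        assert len(kept) == 1 and len(rejected) == 1
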