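import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habwatch.scene_io import MissingBandError, RadiometricMetadata, RasterField, Scene
from habwatch.synthetic_scene import BloomScenario, build_truth, encode_scene
from habwatch.thermal import (
    NdviStats,
    bt_to_radiance,
    dn_to_radiance,
    emissivity,
    invert_mono_window,
    mono_window_lsat,
    ndvi,
    proportional_vegetation,
    radiance_to_bt,
    retrieve_lsat,
)


def _field(values, mask=None, role="x"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if mask is None:
        mask = np.ones(values.shape, bool)
    return RasterField(values, np.atleast_2d(mask), role)


class TestRadiance:
    def test_zero_dn_returns_additive_factor(self, meta):
        out = dn_to_radiance(np.array([[0]]), meta)
        assert out.values[0, 0] == pytest.approx(0.1, abs=1e-15)

    def test_hand_arithmetic_at_10000(self, meta):
        out = dn_to_radiance(np.array([[10000]]), meta)
        assert out.values[0, 0] == pytest.approx(3.442, abs=1e-9)

    def test_affine_in_dn_with_slope_ml(self, meta):
        dn = np.array([[100, 101, 200]])
        out = dn_to_radiance(dn, meta)
        diffs = np.diff(out.values[0]) / np.diff(dn[0].astype(float))
        assert diffs == pytest.approx([meta.ml, meta.ml])


class TestBrightnessTemperature:
    def test_closed_form_inversion_at_300K(self, meta):
        radiance = meta.k1 / (np.exp(meta.k2 / 300.0) - 1.0)
        out = radiance_to_bt(_field([[radiance]]), meta)
        assert out.values[0, 0] == pytest.approx(26.85, abs=1e-9)

    def test_celsius_is_kelvin_minus_27315(self, meta):
        for radiance in (2.0, 5.0, 9.0, 15.0):
            out = radiance_to_bt(_field([[radiance]]), meta)
            kelvin = meta.k2 / np.log(meta.k1 / radiance + 1.0)
            assert kelvin - out.values[0, 0] == pytest.approx(273.15, abs=1e-9)

    def test_strictly_increasing_in_radiance(self, meta):
        radiances = np.linspace(2, 15, 500)[None, :]
        out = radiance_to_bt(_field(radiances), meta)
        assert np.all(np.diff(out.values[0]) > 0)

    def test_nonpositive_radiance_masked(self, meta):
        out = radiance_to_bt(_field([[5.0, 0.0, -1.0]]), meta)
        assert out.mask.tolist() == [[True, False, False]]

    def test_round_trip_with_inverse_within_microkelvin(self, meta):
        radiance = np.linspace(2, 15, 200)[None, :]
        bt = radiance_to_bt(_field(radiance), meta)
        back = bt_to_radiance(bt.values, meta)
        t_orig = meta.k2 / np.log(meta.k1 / radiance + 1.0)
        t_back = meta.k2 / np.log(meta.k1 / back + 1.0)
        assert np.max(np.abs(t_back - t_orig)) < 1e-6


class TestNdvi:
    @pytest.mark.parametrize(
        "red, nir, expected", [(0.1, 0.1, 0.0), (0.1, 0.3, 0.5)]
    )
    def test_values(self, red, nir, expected):
        out = ndvi(_field([[red]]), _field([[nir]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_zero_denominator_masked(self):
        out = ndvi(_field([[0.0]]), _field([[0.0]]))
        assert not out.mask[0, 0]

    def test_bounded_for_nonnegative_inputs(self):
        rng = np.random.default_rng(3)
        red = _field(rng.uniform(0, 1, (20, 20)))
        nir = _field(rng.uniform(0, 1, (20, 20)))
        out = ndvi(red, nir)
        vals = out.valid_values()
        assert np.all(vals >= -1) and np.all(vals <= 1)


class TestPvAndEmissivity:
    def test_anchor_points(self):
        stats = NdviStats(-0.2, 0.6)
        field = _field([[-0.2, 0.6, 0.2]])
        out = proportional_vegetation(field, stats)
        assert out.values[0].tolist() == pytest.approx([0.0, 1.0, 0.25])

    def test_degenerate_range_gives_zero(self):
        out = proportional_vegetation(_field([[0.3, 0.3]]), NdviStats(0.3, 0.3))
        assert np.all(out.values == 0)

    def test_clamped_outside_fixed_stats(self):
        out = proportional_vegetation(_field([[-0.9, 0.9]]), NdviStats(-0.2, 0.6))
        assert out.values[0].tolist() == pytest.approx([0.0, 1.0])

    @pytest.mark.parametrize("pv, eps", [(0.0, 0.986), (1.0, 0.990), (0.5, 0.988)])
    def test_emissivity_values(self, pv, eps):
        out = emissivity(_field([[pv]]))
        assert out.values[0, 0] == pytest.approx(eps, abs=1e-12)

    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_bounds_hold_for_random_ndvi(self, values):
        stats = NdviStats(-1.0, 1.0)
        pv = proportional_vegetation(_field([values]), stats)
        assert np.all((pv.values >= 0) & (pv.values <= 1))
        eps = emissivity(pv)
        assert np.all((eps.values >= 0.986) & (eps.values <= 0.990))

    def test_stats_invariant_enforced(self):
        with pytest.raises(ValueError):
            NdviStats(0.5, -0.5)


class TestMonoWindow:
    def test_unit_emissivity_is_identity(self, meta):
        bt = _field([[17.0, 30.0, 36.8]])
        out = mono_window_lsat(bt, _field(np.full((1, 3), 1.0)), meta)
        assert out.values == pytest.approx(bt.values)

    def test_hand_arithmetic_celsius_mode(self, meta):
        out = mono_window_lsat(_field([[30.0]]), _field([[0.986]]), meta)
        expected = 30.0 / (1.0 + (10.895e-6 * 30.0 / 1.4388e-2) * np.log(0.986))
        assert out.values[0, 0] == pytest.approx(expected, rel=1e-12)
        assert out.values[0, 0] == pytest.approx(30.0096, abs=1e-3)

    def test_unit_modes_differ_and_are_both_close(self, meta):
        bt = _field([[30.0]])
        eps = _field([[0.986]])
        celsius = mono_window_lsat(bt, eps, meta, temp_mode="celsius")
        kelvin = mono_window_lsat(bt, eps, meta, temp_mode="kelvin")
        assert celsius.values[0, 0] != kelvin.values[0, 0]
        # the correction scales with the working temperature, so the Kelvin
        # mode shifts ~10x more than the Celsius mode at lake temperatures
        assert abs(celsius.values[0, 0] - 30.0) < 0.2
        assert 0.2 < abs(kelvin.values[0, 0] - 30.0) < 1.5

    def test_monotone_in_emissivity(self, meta):
        # dense-grid oracle: for fixed Tb > 0 in celsius mode, raising
        # emissivity toward 1 shrinks the correction, lowering LSAT
        eps = np.linspace(0.986, 1.0, 1000)[None, :]
        out = mono_window_lsat(
            _field(np.full((1, 1000), 30.0)), _field(eps), meta
        )
        assert np.all(np.diff(out.values[0]) < 0)

    def test_inverse_round_trip(self, meta):
        lsat = np.array([[17.0, 26.85, 35.0]])
        eps = np.full((1, 3), 0.98644)
        bt = invert_mono_window(lsat, eps, meta)
        out = mono_window_lsat(_field(bt), _field(eps), meta)
        assert out.values == pytest.approx(lsat, abs=1e-10)


class TestRetrieveLsat:
    def test_noiseless_round_trip(self, scene, truth, scenario):
        out = retrieve_lsat(scene, stats=scenario.ndvi_stats)
        assert out.mask.all()
        assert np.max(np.abs(out.values - truth.lsat_truth.values)) <= 0.05

    def test_uniform_ndvi_with_auto_stats_degenerates_to_zero_pv(self, scene, truth):
        # scene has constant red/nir, so auto stats give max = min -> Pv = 0;
        # the emissivity shift from the encoding value is far below 0.05 deg C
        out = retrieve_lsat(scene, stats="auto")
        assert np.max(np.abs(out.values - truth.lsat_truth.values)) <= 0.05

    def test_missing_tir10_rejected(self, meta):
        scene = Scene(
            bands={
                "red": np.full((2, 2), 8000, dtype=np.int32),
                "nir": np.full((2, 2), 7600, dtype=np.int32),
            },
            meta=meta,
        )
        with pytest.raises(MissingBandError, match="tir10"):
            retrieve_lsat(scene)

    def test_all_invalid_ndvi_rejected(self, meta):
        scene = Scene(
            bands={
                "red": np.full((2, 2), -9999, dtype=np.int32),
                "nir": np.full((2, 2), -9999, dtype=np.int32),
                "tir10": np.full((2, 2), 28000, dtype=np.int32),
            },
            meta=meta, nodata=-9999,
        )
        with pytest.raises(ValueError, match="auto-derive"):
            retrieve_lsat(scene, stats="auto")
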