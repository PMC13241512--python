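"""Spectrum vectorization: binning, rendering, resampling, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectromatch.codec import (
    C13_BINS,
    H1_LEN,
    HSQC_SHAPE,
    IR_LEN,
    AugmentationConfig,
    HSQCPeak,
    PeakList1D,
    augment_h1,
    bin_c13,
    minmax01,
    rasterize_hsqc,
    render_ir,
    resample_linear,
    vectorize_h1,
    vectorize_ir,
)


def _c13(positions):
    n = len(positions)
    return PeakList1D("c13", np.asarray(positions, float), np.ones(n), np.zeros(n))


class TestC13Binning:
    @pytest.mark.parametrize(
        "shift,expected_bin",
        [(0.0, 0), (150.0, 256), (300.0, 511), (299.9, 511)],
    )
    def test_shift_maps_to_expected_bin(self, shift, expected_bin):
        vec = bin_c13(_c13([shift]))
        assert vec.values[expected_bin] == 1.0
        assert vec.values.sum() == 1.0

    def test_empty_peak_list_gives_zero_vector(self):
        vec = bin_c13(_c13([]))
        assert vec.values.shape == (C13_BINS,)
        assert not vec.values.any()

    def test_out_of_range_shifts_are_dropped(self):
        vec = bin_c13(_c13([-5.0, 350.0, 100.0]))
        assert vec.values.sum() == 1.0

    def test_vector_is_binary(self):
        vec = bin_c13(_c13([10.0, 10.1, 200.0]))
        assert set(np.unique(vec.values)) <= {0.0, 1.0}

    @given(st.lists(st.floats(0.0, 299.999), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_binning_is_monotone_in_position(self, shifts):
        width = 300.0 / C13_BINS
        idx = [int(s // width) for s in sorted(shifts)]
        assert idx == sorted(idx)

    def test_nonfinite_shift_rejected(self):
        with pytest.raises(ValueError):
            _c13([np.nan])


class TestH1Vectorization:
    def test_output_length_is_10000(self):
        pk = PeakList1D("h1", [1.0], [1.0], [0.02])
        assert vectorize_h1(pk).values.shape == (H1_LEN,)

    def test_flat_zero_trace_gives_zeros(self):
        axis = np.linspace(-2, 10, 100)
        vec = vectorize_h1((axis, np.zeros(100)))
        assert not vec.values.any()

    def test_narrow_peak_at_2ppm_peaks_at_index_3333(self):
        pk = PeakList1D("h1", [2.0], [1.0], [0.01])
        vec = vectorize_h1(pk)
        assert int(np.argmax(vec.values)) == round((2.0 + 2.0) / 12.0 * (H1_LEN - 1))

    def test_values_in_unit_interval(self):
        pk = PeakList1D("h1", [1.0, 7.2], [3.0, 1.0], [0.05, 0.05])
        v = vectorize_h1(pk).values
        assert v.min() >= 0.0 and v.max() == 1.0


class TestIRVectorization:
    def test_output_length_is_1600(self):
        pk = PeakList1D("ir", [1700.0], [0.9], [30.0])
        assert vectorize_ir(pk).values.shape == (IR_LEN,)

    def test_absorption_at_2200_minimizes_index_800(self):
        pk = PeakList1D("ir", [2200.0], [0.8], [20.0])
        vec = vectorize_ir(pk)
        assert int(np.argmin(vec.values)) == int((2200 - 600) / 2)

    def test_empty_trace_is_all_ones_baseline(self):
        raw = render_ir((np.array([]), np.array([])))
        assert np.all(raw == 1.0)

    def test_unmeasured_region_fills_with_baseline(self):
        axis = np.linspace(1000, 1200, 50)
        raw = render_ir((axis, np.full(50, 0.4)))
        assert raw[0] == 1.0 and raw[-1] == 1.0


class TestHSQCRasterization:
    def test_empty_peak_list_gives_zero_grid(self):
        vec = rasterize_hsqc([])
        assert vec.values.shape == HSQC_SHAPE
        assert not vec.values.any()

    def test_grid_argmax_at_centroid_cell(self):
        pk = HSQCPeak(100.0, 99.0, 101.0, 3.0, 2.9, 3.1)
        vec = rasterize_hsqc([pk])
        row, col = np.unravel_index(np.argmax(vec.values), vec.values.shape)
        # independent coordinate-to-cell mapping
        assert row == int(100.0 / (300.0 / 512))
        assert col == int((3.0 + 2.0) / (12.0 / 512))

    def test_out_of_window_peak_dropped(self):
        pk = HSQCPeak(400.0, 399.0, 401.0, 3.0, 2.9, 3.1)
        assert not rasterize_hsqc([pk]).values.any()

    def test_mass_positive_iff_in_window_peak(self):
        inside = HSQCPeak(50.0, 49.0, 51.0, 1.0, 0.9, 1.1)
        assert rasterize_hsqc([inside]).values.sum() > 0

    def test_invalid_extent_rejected(self):
        with pytest.raises(ValueError):
            HSQCPeak(100.0, 101.0, 99.0, 3.0, 2.9, 3.1)


class TestResampleLinear:
    def test_reduces_32768_to_10000(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=32768)
        out = resample_linear(x, 10_000)
        assert out.shape == (10_000,)
        assert out[0] == x[0] and out[-1] == x[-1]

    def test_identity_when_lengths_match(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        np.testing.assert_allclose(resample_linear(x, 4), x)

    def test_linear_ramp_stays_linear(self):
        ramp = np.linspace(0, 1, 5)
        np.testing.assert_allclose(resample_linear(ramp, 9), np.linspace(0, 1, 9),
                                   atol=1e-12)

    def test_rejects_target_below_2(self):
        with pytest.raises(ValueError):
            resample_linear(np.arange(5.0), 1)

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.floats(-5, 5),
        st.floats(-10, 10),
        st.integers(2, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_commutes_with_affine_transforms(self, xs, a, b, m):
        x = np.asarray(xs)
        lhs = resample_linear(a * x + b, m)
        rhs = a * resample_linear(x, m) + b
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestAugmentation:
    def test_zero_scales_are_identity_on_peaks(self):
        pk = PeakList1D("h1", [1.0, 3.0], [1.0, 2.0], [0.02, 0.02])
        out = augment_h1(pk, AugmentationConfig.identity())
        np.testing.assert_array_equal(out.positions, pk.positions)
        np.testing.assert_array_equal(out.widths, pk.widths)

    def test_zero_scales_are_identity_on_vector(self):
        pk = PeakList1D("h1", [1.0], [1.0], [0.05])
        vec = vectorize_h1(pk)
        out = augment_h1(vec, AugmentationConfig.identity())
        np.testing.assert_array_equal(out.values, vec.values)

    def test_same_seed_is_deterministic(self):
        pk = PeakList1D("h1", [1.0, 3.0], [1.0, 2.0], [0.02, 0.02])
        cfg = AugmentationConfig(seed=42)
        a = augment_h1(pk, cfg)
        b = augment_h1(pk, cfg)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_jitter_standard_deviation_matches_scale(self):
        # Monte-Carlo check of the stated noise model
        pk = PeakList1D("h1", [5.0], [1.0], [0.02])
        cfg = AugmentationConfig(position_jitter=0.02, width_broadening=1.0,
                                 noise_scale=0.0, baseline_drift=0.0)
        draws = np.array([
            augment_h1(pk, cfg.with_seed(s)).positions[0] for s in range(1000)
        ])
        assert abs(draws.std() - 0.02) < 0.002
        assert abs(draws.mean() - 5.0) < 0.005

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(position_jitter=-0.1)


@given(st.lists(st.floats(-50, 50), min_size=2, max_size=40))
@settings(deadline=None, max_examples=50)
def test_minmax01_bounds(values):
    out = minmax01(np.asarray(values))
    assert out.min() >= 0.0 and out.max() <= 1.0
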