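"""Image encoders against closed forms and a brute-force transition oracle."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acti2img import (
    blur_pool,
    encode_segment,
    fit_quantile_bins,
    gaf,
    images_to_array,
    mtf,
    normalize_resize,
    paa,
    rp,
    transition_matrix,
)
from acti2img.segment import Segment
from acti2img.io import Group


# -- independent oracle ------------------------------------------------------

def oracle_mtf(x, q, orientation):
    """Explicit pair counting and direct field indexing, loop-based."""
    x = np.asarray(x, dtype=float)
    levels = np.arange(1, q) / q
    edges = np.unique(np.quantile(x, levels))
    edges = edges[edges < x.max()]  # right-closed bins; no empty top bin
    bins = np.array([sum(e < v for e in edges) for v in x])
    n_bins = len(edges) + 1
    counts = np.zeros((n_bins, n_bins))
    for a, b in zip(bins[:-1], bins[1:]):  # a followed by b
        if orientation == "source":
            counts[a, b] += 1
        else:
            counts[b, a] += 1
    w = np.zeros_like(counts)
    for i in range(n_bins):
        total = counts[i].sum()
        w[i] = counts[i] / total if total > 0 else 1.0 / n_bins
    n = len(x)
    field = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            field[i, j] = w[bins[i], bins[j]]
    return field


class TestQuantileBinning:
    def test_median_split(self):
        binning = fit_quantile_bins(np.array([1, 2, 3, 4]), 2)
        assert binning.assign(np.array([1, 2, 3, 4])).tolist() == [0, 0, 1, 1]

    def test_constant_series_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            binning = fit_quantile_bins(np.array([5, 5, 5]), 2)
        assert binning.q_effective == 1
        assert binning.assign(np.array([5, 5, 5])).tolist() == [0, 0, 0]

    def test_q_below_two_rejected(self):
        with pytest.raises(ValueError):
            fit_quantile_bins(np.array([1, 2, 3]), 1)

    def test_every_value_maps_to_exactly_one_bin(self, rng):
        values = rng.integers(0, 10, size=200)
        binning = fit_quantile_bins(values, 8)
        bins = binning.assign(values)
        assert bins.min() >= 0
        assert bins.max() < binning.q_effective


class TestTransitionMatrix:
    def test_source_convention_hand_count(self):
        model = transition_matrix([0, 0, 1, 1], 2, orientation="source")
        assert np.allclose(model.w, [[0.5, 0.5], [0.0, 1.0]])

    def test_destination_convention_is_transpose_count(self):
        model = transition_matrix([0, 0, 1, 1], 2, orientation="destination")
        assert np.allclose(model.w, [[1.0, 0.0], [0.5, 0.5]])

    def test_perfect_alternation(self):
        for orientation in ("source", "destination"):
            model = transition_matrix([0, 1, 0, 1, 0], 2, orientation=orientation)
            assert np.allclose(model.w, [[0, 1], [1, 0]])

    def test_out_of_range_bin_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix([0, 3], 2)

    @given(
        bins=st.lists(st.integers(0, 4), min_size=2, max_size=60),
        orientation=st.sampled_from(["source", "destination"]),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_rows_sum_to_one_on_fuzz_inputs(self, bins, orientation):
        model = transition_matrix(bins, 5, orientation=orientation)
        assert np.allclose(model.w.sum(axis=1), 1.0, atol=1e-9)
        assert model.w.min() >= 0 and model.w.max() <= 1


class TestMTF:
    def test_alternating_series_checkerboard(self):
        field = mtf([0, 1, 0, 1, 0], q=2).pixels
        expected = np.array(
            [[0.0 if (i % 2) == (j % 2) else 1.0 for j in range(5)]
             for i in range(5)]
        )
        assert np.array_equal(field, expected)

    def test_constant_series_uniform_field(self):
        with pytest.warns(UserWarning):
            field = mtf([3, 3, 3, 3], q=4).pixels
        assert np.all(field == field[0, 0])

    def test_pixels_in_unit_interval_and_symmetric_in_bins(self, rng):
        x = rng.integers(0, 50, size=40)
        field = mtf(x, q=4).pixels
        assert field.min() >= 0 and field.max() <= 1

    @pytest.mark.parametrize("orientation", ["source", "destination"])
    def test_matches_brute_force_oracle(self, rng, orientation):
        for _ in range(100):
            n = int(rng.integers(2, 51))
            q = int(rng.integers(2, 9))
            x = rng.integers(0, 20, size=n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                field = mtf(x, q=q, orientation=orientation).pixels
            assert np.allclose(field, oracle_mtf(x, q, orientation), atol=1e-9)


class TestBlurPool:
    def test_identity_kernel(self, rng):
        img = rng.random((6, 6))
        assert np.array_equal(blur_pool(img, 1).pixels, img)

    def test_two_by_two_mean(self):
        out = blur_pool(np.array([[0.0, 1.0], [1.0, 0.0]]), 2)
        assert out.pixels.shape == (1, 1)
        assert out.pixels[0, 0] == pytest.approx(0.5)

    def test_trailing_rows_dropped(self, rng):
        out = blur_pool(rng.random((5, 5)), 2)
        assert out.pixels.shape == (2, 2)

    def test_mean_conservation_over_covered_region(self, rng):
        img = rng.random((12, 12))
        for m in (1, 2, 3, 4, 6):
            k = 12 // m * m
            out = blur_pool(img, m)
            assert out.pixels.mean() == pytest.approx(
                img[:k, :k].mean(), abs=1e-9
            )

    def test_pool_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            blur_pool(np.zeros((3, 3)), 4)


class TestGAF:
    def test_paa_block_means(self):
        assert paa(np.array([1.0, 2.0, 3.0, 4.0]), 2).tolist() == [1.5, 3.5]

    def test_gasf_two_point_extremes(self):
        # values rescale to [1, -1] -> angles 0 and pi
        out = gaf(np.array([4.0, 0.0]), variant="gasf").pixels
        assert np.allclose(out, [[1, -1], [-1, 1]], atol=1e-12)

    def test_gasf_three_point_closed_form(self):
        # rescales to [1, 0, -1] -> angles 0, pi/2, pi
        out = gaf(np.array([2.0, 1.0, 0.0]), variant="gasf").pixels
        assert np.allclose(
            out, [[1, 0, -1], [0, -1, 0], [-1, 0, 1]], atol=1e-12
        )

    def test_gasf_matches_product_closed_form(self, rng):
        values = rng.random(30)
        out = gaf(values, variant="gasf").pixels
        x = np.clip(
            (2 * values - values.max() - values.min())
            / (values.max() - values.min()),
            -1,
            1,
        )
        closed = np.outer(x, x) - np.outer(np.sqrt(1 - x**2), np.sqrt(1 - x**2))
        assert np.allclose(out, closed, atol=1e-9)
        assert np.allclose(out, out.T, atol=1e-12)
        assert np.allclose(np.diag(out), np.cos(2 * np.arccos(x)), atol=1e-9)

    def test_gadf_antisymmetric(self, rng):
        out = gaf(rng.random(20), variant="gadf").pixels
        assert np.allclose(out, -out.T, atol=1e-12)

    def test_constant_series_maps_to_angle_pi_over_two(self):
        with pytest.warns(UserWarning, match="constant"):
            out = gaf(np.array([7.0, 7.0, 7.0]), variant="gasf").pixels
        assert np.allclose(out, -1.0)  # cos(pi/2 + pi/2)


class TestRP:
    def test_constant_series_all_zero(self):
        assert np.all(rp(np.array([3.0, 3.0, 3.0])).pixels == 0)

    def test_pairwise_distances(self):
        out = rp(np.array([0.0, 1.0, 2.0])).pixels
        assert np.array_equal(out, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_symmetry_zero_diagonal_nonnegative(self, rng):
        out = rp(rng.integers(0, 100, size=30)).pixels
        assert np.array_equal(out, out.T)
        assert np.all(np.diag(out) == 0)
        assert np.all(out >= 0)

    def test_thresholded_binary(self):
        out = rp(np.array([0.0, 1.0, 5.0]), threshold=1.0).pixels
        assert set(np.unique(out)) <= {0.0, 1.0}
        assert out[0, 1] == 1.0 and out[0, 2] == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            rp(np.array([1.0, 2.0]), threshold=-0.5)


class TestNormalizeResize:
    def test_identity_on_well_scaled_image(self, rng):
        img = rng.random((32, 32))
        img[0, 0], img[1, 1] = 0.0, 1.0
        out = normalize_resize(img, 32).pixels
        assert np.allclose(out, img, atol=1e-12)

    def test_min_max_rescaling(self):
        out = normalize_resize(np.array([[0.0, 255.0], [255.0, 0.0]]), 8).pixels
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_to_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_resize(np.full((16, 16), 3.0), 8).pixels
        assert np.all(out == 0)

    def test_output_side(self, rng):
        assert normalize_resize(rng.random((90, 90)), 64).pixels.shape == (64, 64)


class TestEncodeSegment:
    def _segment(self, values):
        return Segment("p", Group.CONTROL, 0, len(values), values)

    @pytest.mark.parametrize("encoder", ["mtf", "gasf", "gadf", "rp"])
    def test_pipeline_output_contract(self, rng, encoder):
        seg = self._segment(rng.integers(0, 300, size=180))
        img = encode_segment(seg, encoder=encoder, size=64)
        assert img.pixels.shape == (64, 64)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        assert img.source is seg

    def test_deterministic(self, rng):
        values = rng.integers(0, 300, size=180)
        a = encode_segment(self._segment(values)).pixels
        b = encode_segment(self._segment(values.copy())).pixels
        assert np.array_equal(a, b)

    def test_images_to_array_shape(self, rng):
        segs = [self._segment(rng.integers(0, 10, size=60)) for _ in range(3)]
        batch = images_to_array([encode_segment(s, size=32) for s in segs])
        assert batch.shape == (3, 32, 32, 1)
        assert batch.dtype == np.float32
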