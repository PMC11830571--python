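"""Canopy structural complexity metrics against direct examples and
brute-force oracles."""

import math

import numpy as np
import pytest

from structura import canopy
from structura.grids import ElevationGrid, aggregate

import _oracles as oracle


def pixels_of(values):
    return aggregate(ElevationGrid(np.asarray(values, dtype=float), 1.0), 1.0)


class TestPercentileHeight:
    def test_constant(self):
        assert canopy.percentile_height(pixels_of(np.full((3, 3), 7.0))) == 7.0

    def test_uniform_integers_linear_interpolation(self):
        h = np.arange(101.0).reshape(1, -1)
        assert canopy.percentile_height(pixels_of(h)) == pytest.approx(oracle.quantile_linear(h.ravel(), 0.95))
        assert canopy.percentile_height(pixels_of(h)) == pytest.approx(95.0)

    def test_q1_is_max(self, rng):
        h = rng.uniform(0, 30, (5, 5))
        assert canopy.percentile_height(pixels_of(h), q=1.0) == pytest.approx(h.max())


class TestMochAndRugosity:
    def test_moch_mean(self):
        assert canopy.moch(pixels_of([[10.0, 20.0]])) == 15.0
        assert canopy.moch(pixels_of([[1.0, 2.0], [3.0, 4.0]])) == 2.5

    def test_cr_two_values(self):
        assert canopy.canopy_rugosity(pixels_of([[0.0, 10.0]])) == pytest.approx(5.0)

    def test_cr_zero_for_constant(self):
        assert canopy.canopy_rugosity(pixels_of(np.full((4, 4), 9.0))) == 0.0

    def test_cr_translation_invariant_scale_linear(self, rng):
        h = rng.uniform(0, 25, (6, 6))
        cr = canopy.canopy_rugosity(pixels_of(h))
        assert canopy.canopy_rugosity(pixels_of(h + 13.0)) == pytest.approx(cr)
        assert canopy.canopy_rugosity(pixels_of(h * 3.0)) == pytest.approx(3 * cr)

    def test_variance_form(self, rng):
        h = rng.uniform(0, 25, (6, 6))
        assert canopy.canopy_rugosity(pixels_of(h), variance=True) == pytest.approx(
            canopy.canopy_rugosity(pixels_of(h)) ** 2
        )


class TestEntropyVCI:
    def test_single_bin_zero(self):
        assert canopy.entropy(np.full(10, 3.2)) == 0.0

    def test_uniform_four_bins(self):
        h = np.array([0.6, 1.6, 2.6, 3.6])
        assert canopy.entropy(h) == pytest.approx(math.log(4))
        assert canopy.vci(h) == pytest.approx(1.0)

    def test_direct_proportions(self):
        # proportions (0.5, 0.25, 0.25) over three bins
        h = np.array([0.6, 0.7, 1.6, 2.6])
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert canopy.entropy(h) == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_no_vegetation_warns_zero(self):
        with pytest.warns(UserWarning):
            assert canopy.entropy(np.zeros(5)) == 0.0

    def test_vci_bounds(self, rng):
        h = rng.uniform(0, 30, 500)
        assert 0.0 <= canopy.vci(h) <= 1.0

    def test_vci_single_bin_zero(self):
        assert canopy.vci(np.full(6, 1.2)) == 0.0


class TestVAI:
    def test_bare_ground_zero(self):
        assert canopy.vai(np.zeros(12)) == 0.0

    def test_homogeneous_canopy_matches_slice_oracle(self):
        h = np.full(25, 10.0)
        assert canopy.vai(h) == pytest.approx(oracle.vai_slices(h), rel=1e-12)

    def test_monotone_in_canopy_lift(self, rng):
        h = rng.uniform(0.5, 12.0, 100)
        h[rng.random(100) < 0.3] = 0.0
        lifted = np.where(h > 0, h + 1.0, 0.0)
        assert canopy.vai(lifted) > canopy.vai(h)

    def test_matches_oracle_random(self, rng):
        for _ in range(10):
            h = rng.uniform(0, 20, 40)
            h[rng.random(40) < 0.2] = 0.0
            assert canopy.vai(h) == pytest.approx(oracle.vai_slices(h), rel=1e-9)


class TestRumple:
    def test_flat_is_one(self, flat_chm):
        assert canopy.rumple(flat_chm) == pytest.approx(1.0)

    def test_tilted_plane_sqrt10(self):
        g = ElevationGrid(np.array([[0.0, 0.0], [3.0, 3.0]]), 1.0)
        assert canopy.rumple(g) == pytest.approx(math.sqrt(10), rel=1e-12)

    def test_at_least_one_and_matches_oracle(self, rng):
        for _ in range(10):
            z = rng.uniform(0, 15, (6, 7))
            g = ElevationGrid(z, 1.0)
            r = canopy.rumple(g)
            assert r >= 1.0
            assert r == pytest.approx(oracle.rumple_surface(z, 1.0), rel=1e-9)

    def test_translation_invariant(self, rng):
        z = rng.uniform(0, 15, (5, 5))
        assert canopy.rumple(ElevationGrid(z, 1.0)) == pytest.approx(
            canopy.rumple(ElevationGrid(z + 40.0, 1.0)), rel=1e-12
        )

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            canopy.rumple(ElevationGrid(np.ones((1, 4)), 1.0))


class TestGapFractions:
    def test_counting(self):
        h = np.array([0, 0, 0, 5, 5, 5, 5, 5, 5, 5], dtype=float)
        dgf, cf = canopy.gap_fractions(h)
        assert dgf == pytest.approx(0.3)
        assert cf == pytest.approx(0.7)

    def test_all_vegetated(self):
        dgf, cf = canopy.gap_fractions(np.full(9, 2.0))
        assert dgf == 0.0 and cf == 1.0

    def test_complement(self, rng):
        h = rng.choice([0.0, 3.0, 8.0], 50)
        dgf, cf = canopy.gap_fractions(h)
        assert dgf + cf == pytest.approx(1.0)


class TestCanopyMetricsSweep:
    def test_flat_canopy_suite(self, flat_chm):
        m = canopy.canopy_metrics(flat_chm, 1.0)
        assert m["rumple"] == pytest.approx(1.0)
        assert m["cr"] == 0.0
        assert m["entropy"] == 0.0
        assert m["vci"] == 0.0
        assert m["dgf"] + m["cf"] == pytest.approx(1.0)
        assert m["q95"] == 12.0 and m["moch"] == 12.0

    def test_grain_aggregation_uses_pixel_maxima(self):
        chm = ElevationGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 1.0)
        m = canopy.canopy_metrics(chm, 2.0)
        assert m["moch"] == 4.0  # single pixel, max 4

    def test_deterministic(self, rng):
        z = rng.uniform(0, 20, (20, 20))
        chm = ElevationGrid(z, 1.0)
        a = canopy.canopy_metrics(chm, 5.0)
        b = canopy.canopy_metrics(chm, 5.0)
        assert a == b
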