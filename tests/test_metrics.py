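"""Local-activity metrics: Kendall's W / ReHo, ALFF, fALFF, standardization,
smoothing — each validated against an independent brute-force oracle."""

import numpy as np
import pytest
from scipy.stats import rankdata

from imgtx.images import ActivityMap, TimeSeriesVolume
from imgtx.metrics import (
    alff_map,
    falff_map,
    gaussian_smooth,
    kendalls_w,
    normalize_by_global_mean,
    reho_map,
)
from .conftest import make_tone


def brute_force_w(series_set):
    """Independent evaluation of Kendall's W from explicit rank sums."""
    K, n = series_set.shape
    rank_rows = [rankdata(row) for row in series_set]
    rank_sums = [sum(rank_rows[k][i] for k in range(K)) for i in range(n)]
    mean_sum = sum(rank_sums) / n
    s = sum((r - mean_sum) ** 2 for r in rank_sums)
    return 12.0 * s / (K**2 * (n**3 - n))


def brute_force_amplitudes(x, tr):
    """One-sided amplitude spectrum 2|X_k|/n by direct DFT summation."""
    n = len(x)
    amps, freqs = [], []
    for k in range(n // 2 + 1):
        re = sum(x[t] * np.cos(2 * np.pi * k * t / n) for t in range(n))
        im = sum(-x[t] * np.sin(2 * np.pi * k * t / n) for t in range(n))
        amps.append(2.0 * np.hypot(re, im) / n)
        freqs.append(k / (n * tr))
    return np.array(amps), np.array(freqs)


class TestKendallsW:
    def test_identical_series_give_one(self, rng):
        x = rng.standard_normal(20)
        assert kendalls_w(np.tile(x, (27, 1))) == pytest.approx(1.0)

    def test_reversed_rank_orders_give_zero(self):
        # two series with exactly opposite orderings: all rank sums equal
        assert kendalls_w(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])) == pytest.approx(0.0)

    def test_hand_rank_instance_matches_brute_force(self):
        ranks = np.array([[1, 2, 3, 4], [2, 1, 3, 4], [1, 3, 2, 4]], float)
        assert kendalls_w(ranks) == pytest.approx(brute_force_w(ranks), abs=1e-14)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            K = rng.integers(2, 6)
            n = rng.integers(2, 7)
            x = rng.standard_normal((K, n))
            if rng.random() < 0.3:  # inject ties
                x = np.round(x)
                if np.any(x.std(axis=1) == 0):
                    continue
            assert abs(kendalls_w(x) - brute_force_w(x)) < 1e-12

    def test_constant_series_returns_zero(self):
        x = np.vstack([np.ones(5), np.arange(5.0)])
        assert kendalls_w(x) == 0.0

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal((4, 10))
        w0 = kendalls_w(x)
        assert kendalls_w(np.exp(x)) == pytest.approx(w0)
        assert kendalls_w(x**3) == pytest.approx(w0)


class TestRehoMap:
    def test_shared_series_give_unit_map(self, rng):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        series = rng.standard_normal(30)
        data = np.broadcast_to(series, (5, 5, 5, 30)).copy()
        vol = TimeSeriesVolume(data, affine, 2.0)
        mask = np.ones((5, 5, 5), bool)
        out = reho_map(vol, mask)
        np.testing.assert_allclose(out.data, 1.0)

    def test_matches_per_voxel_brute_force(self, rng):
        vol = TimeSeriesVolume(rng.standard_normal((5, 5, 5, 25)), np.eye(4), 2.0)
        mask = rng.random((5, 5, 5)) > 0.2
        mask[2, 2, 2] = True
        out = reho_map(vol, mask)
        for ijk in [(0, 0, 0), (2, 2, 2), (4, 4, 1), (1, 3, 2)]:
            if not mask[ijk]:
                continue
            nb = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        p = (ijk[0] + di, ijk[1] + dj, ijk[2] + dk)
                        if all(0 <= c < 5 for c in p) and mask[p]:
                            nb.append(vol.data[p])
            nb = np.array(nb)
            expected = brute_force_w(nb) if len(nb) >= 2 else 0.0
            assert out.data[ijk] == pytest.approx(expected, abs=1e-12)

    def test_white_noise_mean_is_low(self, rng):
        vol = TimeSeriesVolume(rng.standard_normal((5, 5, 5, 230)), np.eye(4), 2.0)
        mask = np.ones((5, 5, 5), bool)
        out = reho_map(vol, mask)
        assert out.data[mask].mean() < 0.15

    def test_coherent_region_exceeds_background(self, rng):
        data = rng.standard_normal((8, 8, 8, 40))
        shared = rng.standard_normal(40)
        data[2:5, 2:5, 2:5] += 1.0 * shared
        vol = TimeSeriesVolume(data, np.eye(4), 2.0)
        mask = np.ones((8, 8, 8), bool)
        out = reho_map(vol, mask)
        inside = out.data[2:5, 2:5, 2:5].mean()
        outside = out.data[~np.isin(np.arange(8), [2, 3, 4])[:, None, None] & mask].mean()
        assert inside > outside

    def test_empty_mask_errors(self, small_volume):
        with pytest.raises(ValueError):
            reho_map(small_volume, np.zeros((6, 6, 6), bool))


class TestAlff:
    def _vol(self, series, tr=2.0):
        n = len(series)
        return TimeSeriesVolume(np.broadcast_to(series, (2, 2, 2, n)).copy(), np.eye(4), tr)

    def test_constant_series_gives_zero(self, full_mask):
        vol = self._vol(np.full(100, 5.0))
        mask = np.ones((2, 2, 2), bool)
        assert alff_map(vol, mask).data.max() == 0.0

    def test_pure_tone_matches_brute_force(self):
        n, tr, A = 100, 2.0, 1.7
        tone = make_tone(0.05, n, tr, amplitude=A)
        vol = self._vol(tone, tr)
        mask = np.ones((2, 2, 2), bool)
        out = alff_map(vol, mask)
        amps, freqs = brute_force_amplitudes(tone, tr)
        band = (freqs >= 0.01) & (freqs <= 0.1) & (freqs > 0)
        expected = amps[band].mean()
        assert out.data[0, 0, 0] == pytest.approx(expected, abs=1e-10)
        # single-bin tone: the bin amplitude equals A under the 2|X|/n convention
        assert amps[band].max() == pytest.approx(A, abs=1e-9)

    def test_homogeneous_of_degree_one(self, rng):
        series = rng.standard_normal(120)
        mask = np.ones((2, 2, 2), bool)
        a1 = alff_map(self._vol(series), mask).data[0, 0, 0]
        a2 = alff_map(self._vol(2 * series), mask).data[0, 0, 0]
        assert a2 == pytest.approx(2 * a1)

    def test_too_few_band_bins_errors(self):
        # 6 points at TR 2 s: only one frequency bin (1/12 Hz) inside the band
        vol = self._vol(np.arange(6.0))
        with pytest.raises(ValueError):
            alff_map(vol, np.ones((2, 2, 2), bool))


class TestFalff:
    def _vol(self, series, tr=2.0):
        n = len(series)
        return TimeSeriesVolume(np.broadcast_to(series, (2, 2, 2, n)).copy(), np.eye(4), tr)

    def test_band_limited_signal_gives_one(self):
        tone = make_tone(0.05, 200, 2.0)
        out = falff_map(self._vol(tone), np.ones((2, 2, 2), bool))
        assert out.data[0, 0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_out_of_band_signal_gives_zero(self):
        tone = make_tone(0.2, 200, 2.0)
        out = falff_map(self._vol(tone), np.ones((2, 2, 2), bool))
        assert out.data[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_equal_tones_split_matches_brute_force(self):
        n, tr = 200, 2.0
        mix = make_tone(0.05, n, tr) + make_tone(0.2, n, tr)
        out = falff_map(self._vol(mix, tr), np.ones((2, 2, 2), bool))
        amps, freqs = brute_force_amplitudes(mix, tr)
        band = (freqs >= 0.01) & (freqs <= 0.1) & (freqs > 0)
        expected = amps[band].sum() / amps[freqs > 0].sum()
        assert out.data[0, 0, 0] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.5, abs=1e-6)

    def test_scale_invariant(self, rng):
        series = rng.standard_normal(120)
        mask = np.ones((2, 2, 2), bool)
        f1 = falff_map(self._vol(series), mask).data[0, 0, 0]
        f2 = falff_map(self._vol(5 * series), mask).data[0, 0, 0]
        assert f2 == pytest.approx(f1)

    def test_constant_voxel_flagged_zero(self):
        out = falff_map(self._vol(np.full(100, 3.0)), np.ones((2, 2, 2), bool))
        assert out.data.max() == 0.0


class TestGlobalMeanNormalization:
    def test_uniform_map_becomes_ones(self):
        amap = ActivityMap(np.full((4, 4, 4), 7.0), np.eye(4), "reho")
        mask = np.ones((4, 4, 4), bool)
        np.testing.assert_allclose(normalize_by_global_mean(amap, mask).data, 1.0)

    def test_in_mask_mean_is_one(self, rng):
        amap = ActivityMap(rng.random((5, 5, 5)) + 0.1, np.eye(4), "alff")
        mask = rng.random((5, 5, 5)) > 0.4
        out = normalize_by_global_mean(amap, mask)
        assert out.data[mask].mean() == pytest.approx(1.0)
        assert out.label == "malff"

    def test_two_voxel_hand_case(self):
        data = np.zeros((2, 1, 1))
        data[0, 0, 0], data[1, 0, 0] = 2.0, 4.0
        mask = np.ones((2, 1, 1), bool)
        out = normalize_by_global_mean(ActivityMap(data, np.eye(4)), mask)
        np.testing.assert_allclose(out.data.ravel(), [2 / 3, 4 / 3])

    def test_nonpositive_mean_errors(self):
        amap = ActivityMap(np.zeros((2, 2, 2)), np.eye(4))
        with pytest.raises(ValueError):
            normalize_by_global_mean(amap, np.ones((2, 2, 2), bool))


class TestGaussianSmooth:
    def test_delta_profile_matches_analytic_gaussian(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        out = gaussian_smooth(ActivityMap(data, affine), fwhm_mm=6.0)
        sigma_mm = 6.0 / (2 * np.sqrt(2 * np.log(2)))
        ratio = out.data[5, 4, 4] / out.data[4, 4, 4]
        assert ratio == pytest.approx(np.exp(-(3.0**2) / (2 * sigma_mm**2)), rel=0.02)

    def test_uniform_interior_unchanged(self):
        out = gaussian_smooth(ActivityMap(np.ones((15, 15, 15)), np.eye(4)), fwhm_mm=2.0)
        assert out.data[7, 7, 7] == pytest.approx(1.0, abs=1e-6)

    def test_fwhm_zero_is_identity(self, rng):
        amap = ActivityMap(rng.random((4, 4, 4)), np.eye(4))
        np.testing.assert_array_equal(gaussian_smooth(amap, 0.0).data, amap.data)

    def test_mass_conserved_and_nonnegative(self, rng):
        data = np.zeros((12, 12, 12))
        data[4:8, 4:8, 4:8] = rng.random((4, 4, 4))
        out = gaussian_smooth(ActivityMap(data, np.diag([3, 3, 3, 1.0])), fwhm_mm=6.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=0.01)
        assert (out.data >= 0).all()
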