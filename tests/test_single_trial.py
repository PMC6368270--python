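"""Matched difference images: equating, P45 sorting, smoothing, RT sorting."""

import numpy as np
import pytest

from stncc import (
    ERPImage, P45_WINDOW, equate_counts, gaussian_smooth_rows,
    matched_difference, moving_average_rows, p45_amplitude, sort_by_rt,
)


def _image(data, rts=None):
    n, t = data.shape
    return ERPImage(data=data, time_axis=np.arange(-50, t - 50) * 4.0,
                    channel="Pz", trial_ids=np.arange(n),
                    rts=rts if rts is not None else np.full(n, np.nan))


class TestEquateCounts:
    def test_equal_sizes_identity(self, rng):
        a, b = rng.standard_normal((5, 10)), rng.standard_normal((5, 10))
        a2, b2, ka, kb = equate_counts(a, b, seed=0)
        np.testing.assert_array_equal(a2, a)
        np.testing.assert_array_equal(b2, b)

    def test_minimum_rule(self, rng):
        a, b = rng.standard_normal((100, 4)), rng.standard_normal((80, 4))
        a2, b2, ka, kb = equate_counts(a, b, seed=1)
        assert len(a2) == len(b2) == 80

    def test_same_seed_same_removal_and_order_preserved(self, rng):
        a, b = rng.standard_normal((30, 4)), rng.standard_normal((20, 4))
        _, _, ka1, _ = equate_counts(a, b, seed=9)
        _, _, ka2, _ = equate_counts(a, b, seed=9)
        np.testing.assert_array_equal(ka1, ka2)
        assert (np.diff(ka1) > 0).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            equate_counts(np.zeros((0, 4)), np.zeros((3, 4)), seed=0)


class TestP45Amplitude:
    def test_constant_trial(self, time_axis_250):
        assert p45_amplitude(np.full(176, 2.0),
                             time_axis_250) == pytest.approx(2.0)

    def test_boxcar_bump_in_window(self, time_axis_250):
        trace = np.where((time_axis_250 >= 129) & (time_axis_250 <= 141),
                         6.0, 0.0)
        assert p45_amplitude(trace, time_axis_250) == pytest.approx(6.0)

    def test_matches_enumeration(self, rng, time_axis_250):
        trace = rng.standard_normal(176)
        lo, hi = P45_WINDOW.bounds()
        expect = np.mean([v for v, t in zip(trace, time_axis_250)
                          if lo <= t <= hi])
        assert p45_amplitude(trace, time_axis_250) == pytest.approx(expect)


class TestMatchedDifference:
    def test_identical_sets_give_zero_image(self, rng, time_axis_250):
        trials = rng.standard_normal((12, 176))
        img = matched_difference(trials, trials.copy(), time_axis_250, seed=0)
        np.testing.assert_allclose(img.data, 0.0, atol=1e-12)

    def test_zero_contra_returns_sorted_ipsi(self, rng, time_axis_250):
        trials = rng.standard_normal((10, 176))
        img = matched_difference(trials, np.zeros_like(trials),
                                 time_axis_250, seed=0)
        amps = p45_amplitude(trials, time_axis_250)
        np.testing.assert_allclose(img.data, trials[np.argsort(amps)])

    def test_pairing_matches_sort_and_zip_oracle(self, rng, time_axis_250):
        # trials are flat traces, so P45 amplitude == trace value
        vals_i = rng.permutation(10).astype(float)
        vals_c = rng.permutation(10).astype(float)
        ipsi = np.tile(vals_i[:, None], (1, 176))
        contra = np.tile(vals_c[:, None], (1, 176))
        img = matched_difference(ipsi, contra, time_axis_250, seed=0)
        expect = np.sort(vals_i) - np.sort(vals_c)
        np.testing.assert_allclose(img.data[:, 0], expect)

    def test_grand_mean_equals_erp_difference(self, rng, time_axis_250):
        ipsi = rng.standard_normal((15, 176))
        contra = rng.standard_normal((15, 176))
        img = matched_difference(ipsi, contra, time_axis_250, seed=3)
        np.testing.assert_allclose(img.data.mean(axis=0),
                                   ipsi.mean(axis=0) - contra.mean(axis=0),
                                   atol=1e-9)

    def test_row_rts_follow_ipsi_member(self, rng, time_axis_250):
        vals = np.arange(6, dtype=float)
        ipsi = np.tile(vals[::-1][:, None], (1, 176))
        contra = np.zeros((6, 176))
        rts = 100.0 + vals[::-1]       # rt encodes the trial's P45 value
        img = matched_difference(ipsi, contra, time_axis_250, seed=0,
                                 ipsi_rts=rts)
        np.testing.assert_allclose(img.rts - 100.0, img.data[:, 0])


class TestMovingAverageRows:
    def test_constant_image_unchanged(self):
        img = _image(np.full((8, 20), 3.0))
        np.testing.assert_allclose(moving_average_rows(img, 5).data, 3.0)

    def test_width_one_identity(self, rng):
        img = _image(rng.standard_normal((6, 20)))
        np.testing.assert_array_equal(moving_average_rows(img, 1).data,
                                      img.data)

    def test_six_row_ramp_matches_truncated_windows(self):
        data = np.arange(6, dtype=float)[:, None] * np.ones((1, 4))
        img = _image(data)
        out = moving_average_rows(img, 5).data[:, 0]
        expect = [np.mean([j for j in range(max(0, i - 2), min(6, i + 3))])
                  for i in range(6)]
        np.testing.assert_allclose(out, expect)

    def test_bad_width_raises(self, rng):
        img = _image(rng.standard_normal((4, 10)))
        with pytest.raises(ValueError):
            moving_average_rows(img, 4)
        with pytest.raises(ValueError, match="exceeds"):
            moving_average_rows(img, 5)

    def test_rt_smoothing_recorded_and_raw_kept(self, rng):
        rts = np.array([300.0, 320.0, np.nan, 280.0, 290.0])
        img = _image(rng.standard_normal((5, 10)), rts)
        out = moving_average_rows(img, 3)
        np.testing.assert_array_equal(out.rts, rts)
        assert out.rts_smoothed[0] == pytest.approx(310.0)
        assert out.rts_smoothed[2] == pytest.approx(300.0)  # NaN ignored


class TestGaussianSmoothRows:
    def test_constant_unchanged(self):
        img = _image(np.full((20, 10), 2.0))
        np.testing.assert_allclose(gaussian_smooth_rows(img, 2.0).data, 2.0,
                                   atol=1e-9)

    def test_single_row_spreads_as_kernel(self):
        # interior rows, where no edge truncation applies
        data = np.zeros((41, 1))
        data[20] = 1.0
        out = gaussian_smooth_rows(_image(data), 2.0).data[:, 0]
        k = np.exp(-0.5 * (np.arange(-6, 7) / 2.0) ** 2)
        k /= k.sum()
        np.testing.assert_allclose(out[14:27], k, atol=1e-12)

    def test_tiny_sd_is_identity(self, rng):
        img = _image(rng.standard_normal((10, 5)))
        np.testing.assert_allclose(gaussian_smooth_rows(img, 1e-6).data,
                                   img.data, atol=1e-6)


class TestSortByRt:
    def _diff_image(self, rts, rng):
        from stncc import DifferenceImage
        n = len(rts)
        return DifferenceImage(
            data=rng.standard_normal((n, 10)),
            time_axis=np.arange(-2, 8) * 4.0, channel="Pz",
            trial_ids=np.arange(n), rts=np.asarray(rts, float))

    def test_sorted_input_unchanged(self, rng):
        img = self._diff_image([100.0, 200.0, 300.0], rng)
        out = sort_by_rt(img, use_smoothed=False)
        np.testing.assert_array_equal(out.data, img.data)

    def test_reverse_input_reversed(self, rng):
        img = self._diff_image([300.0, 200.0, 100.0], rng)
        out = sort_by_rt(img, use_smoothed=False)
        np.testing.assert_array_equal(out.data, img.data[::-1])

    def test_matches_stable_sort_oracle_and_drops_nan(self, rng):
        rts = rng.integers(200, 240, size=30).astype(float)
        rts[[3, 17]] = np.nan
        img = self._diff_image(rts, rng)
        out = sort_by_rt(img, use_smoothed=False)
        keep = np.flatnonzero(np.isfinite(rts))
        order = keep[np.argsort(rts[keep], kind="stable")]
        np.testing.assert_array_equal(out.data, img.data[order])
        assert out.n_rows == 28
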