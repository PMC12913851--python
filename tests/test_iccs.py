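"""ICCS estimator against a brute-force pair-sum oracle, plus the
invariances that define the colocalization fraction."""

import numpy as np
import pytest

from chromodyn import (
    InsufficientRegionError,
    NormalizationError,
    TimelapseStack,
    blob_texture,
    coloc_fractions,
    fit_amplitude,
    masked_correlation,
    timelapse_iccs,
)
from chromodyn.iccs import CorrelationSurface


def brute_force_correlation(a, b, mask, max_lag):
    """Independent oracle: nested-loop pair sums over in-mask pixel pairs.

    G(dy, dx) = <da(x) db(x+lag)>_pairs / (<a><b>), matching the estimator
    definition but computed without FFTs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mask = np.asarray(mask, bool)
    mean_a, mean_b = a[mask].mean(), b[mask].mean()
    da = np.where(mask, a - mean_a, 0.0)
    db = np.where(mask, b - mean_b, 0.0)
    size = 2 * max_lag + 1
    g = np.full((size, size), np.nan)
    rows, cols = a.shape
    for dy in range(-max_lag, max_lag + 1):
        for dx in range(-max_lag, max_lag + 1):
            total, count = 0.0, 0
            for y in range(rows):
                for x in range(cols):
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < rows and 0 <= x2 < cols and mask[y, x] and mask[y2, x2]:
                        total += da[y, x] * db[y2, x2]
                        count += 1
            if count:
                g[dy + max_lag, dx + max_lag] = total / count / (mean_a * mean_b)
    return g


def gaussian_surface(g0, width, offset=0.0, max_lag=16):
    lags = np.arange(-max_lag, max_lag + 1)
    yy, xx = np.meshgrid(lags, lags, indexing="ij")
    vals = g0 * np.exp(-(yy**2 + xx**2) / width**2) + offset
    return CorrelationSurface(
        values=vals, lags_px=lags, n_pairs=np.full_like(vals, 1000.0)
    )


class TestMaskedCorrelation:
    def test_matches_bruteforce_full_mask(self, rng):
        a = rng.poisson(20.0, (16, 16)).astype(float)
        b = rng.poisson(20.0, (16, 16)).astype(float)
        mask = np.ones((16, 16), bool)
        surf = masked_correlation(a, b, mask, max_lag=8)
        oracle = brute_force_correlation(a, b, mask, max_lag=8)
        np.testing.assert_allclose(surf.values, oracle, atol=1e-8)

    def test_matches_bruteforce_irregular_mask(self, rng):
        a = rng.poisson(15.0, (16, 16)).astype(float)
        b = a + rng.normal(0, 2, (16, 16))
        mask = rng.random((16, 16)) > 0.4
        if mask.sum() < 100:  # keep the precondition satisfied
            mask[:8] = True
        surf = masked_correlation(a, b, mask, max_lag=6)
        oracle = brute_force_correlation(a, b, mask, max_lag=6)
        np.testing.assert_allclose(surf.values, oracle, atol=1e-8)

    def test_zero_lag_is_variance_over_mean_squared(self, rng):
        img = rng.poisson(30.0, (32, 32)).astype(float)
        mask = np.ones((32, 32), bool)
        surf = masked_correlation(img, img, mask)
        expected = img.var() / img.mean() ** 2  # closed form on the realized image
        assert surf.zero_lag == pytest.approx(expected, rel=1e-10)

    def test_constant_images_give_zero_surface(self):
        img = np.full((32, 32), 5.0)
        surf = masked_correlation(img, img, np.ones((32, 32), bool))
        assert np.nanmax(np.abs(surf.values)) == pytest.approx(0.0, abs=1e-12)

    def test_pair_count_at_zero_lag_is_mask_size(self, rng):
        img = rng.random((32, 32)) + 1
        mask = rng.random((32, 32)) > 0.3
        surf = masked_correlation(img, img, mask)
        c = surf.max_lag
        assert surf.n_pairs[c, c] == mask.sum()

    def test_acf_symmetric_under_lag_negation(self, rng):
        img = rng.poisson(20.0, (32, 32)).astype(float)
        surf = masked_correlation(img, img, np.ones((32, 32), bool), max_lag=8)
        np.testing.assert_allclose(surf.values, surf.values[::-1, ::-1], atol=1e-10)

    def test_small_mask_refused(self, rng):
        img = rng.random((16, 16)) + 1
        mask = np.zeros((16, 16), bool)
        mask[:5, :5] = True
        with pytest.raises(InsufficientRegionError):
            masked_correlation(img, img, mask)

    def test_zero_mean_refused(self):
        img = np.zeros((16, 16))
        with pytest.raises(NormalizationError):
            masked_correlation(img, img, np.ones((16, 16), bool))


class TestFitAmplitude:
    def test_model_on_model_recovery(self):
        fit = fit_amplitude(gaussian_surface(0.5, 4.0), exclude_zero_lag=False)
        assert fit.success
        assert fit.g0 == pytest.approx(0.5, abs=1e-6)
        assert fit.width_px == pytest.approx(4.0, abs=1e-4)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)

    def test_zero_lag_spike_excluded_from_extrapolation(self):
        surf = gaussian_surface(0.5, 4.0)
        c = surf.max_lag
        surf.values[c, c] += 0.3  # shot-noise spike
        fit = fit_amplitude(surf, exclude_zero_lag=True)
        assert fit.g0 == pytest.approx(0.5, abs=1e-6)

    def test_negative_amplitude_preserved(self):
        fit = fit_amplitude(gaussian_surface(-0.2, 4.0))
        assert fit.success
        assert fit.g0 == pytest.approx(-0.2, abs=1e-6)


class TestColocFractions:
    def test_identical_channels_give_unity(self):
        img = blob_texture((128, 128), 60, 3.0, 3.0, seed=4)
        res = coloc_fractions(img, img, np.ones(img.shape, bool))
        assert res.valid
        assert res.f1 == pytest.approx(1.0, abs=0.05)
        assert res.f2 == pytest.approx(1.0, abs=0.05)

    def test_independent_channels_average_to_zero(self):
        vals = []
        for seed in range(10):
            a = blob_texture((128, 128), 60, 3.0, 3.0, seed=seed)
            b = blob_texture((128, 128), 60, 3.0, 3.0, seed=seed + 500)
            vals.append(coloc_fractions(a, b, np.ones(a.shape, bool)).f1)
        assert np.mean(vals) == pytest.approx(0.0, abs=0.05)

    def test_equal_mean_inversion_gives_minus_one(self):
        img = blob_texture((128, 128), 60, 3.0, 3.0, seed=4)
        inverted = 2 * img.mean() - img
        res = coloc_fractions(img, inverted, np.ones(img.shape, bool))
        assert res.f1 == pytest.approx(-1.0, abs=0.05)

    def test_scale_invariance(self):
        img1 = blob_texture((128, 128), 60, 3.0, 3.0, seed=4)
        img2 = blob_texture((128, 128), 60, 3.0, 3.0, seed=5)
        mask = np.ones(img1.shape, bool)
        base = coloc_fractions(img1, img2, mask)
        scaled = coloc_fractions(3.7 * img1, 0.2 * img2, mask)
        assert scaled.f1 == pytest.approx(base.f1, abs=1e-6)
        assert scaled.f2 == pytest.approx(base.f2, abs=1e-6)

    def test_translation_invariance_with_mask(self):
        img1 = blob_texture((128, 128), 60, 3.0, 3.0, seed=4)
        img2 = blob_texture((128, 128), 60, 3.0, 3.0, seed=5)
        mask = np.zeros(img1.shape, bool)
        mask[30:80, 30:80] = True
        base = coloc_fractions(img1, img2, mask)
        shift = (17, -9)
        moved = coloc_fractions(
            np.roll(img1, shift, (0, 1)),
            np.roll(img2, shift, (0, 1)),
            np.roll(mask, shift, (0, 1)),
        )
        assert moved.f1 == pytest.approx(base.f1, abs=1e-9)

    def test_inversion_flips_cross_amplitude_sign(self):
        img1 = blob_texture((128, 128), 60, 3.0, 3.0, seed=4)
        img2 = blob_texture((128, 128), 60, 3.0, 3.0, seed=5)
        mask = np.ones(img1.shape, bool)
        plus = coloc_fractions(img1, img2, mask).gcc0
        minus = coloc_fractions(img1, 2 * img2.mean() - img2, mask).gcc0
        assert minus == pytest.approx(-plus, abs=1e-9)


class TestTimelapseIccs:
    @staticmethod
    def _stack_and_masks(frames_ch1, frames_ch2):
        n = len(frames_ch1)
        data = np.stack([np.stack(frames_ch1), np.stack(frames_ch2)], axis=1)
        time_s = np.arange(n, dtype=float) + 2.6
        stack = TimelapseStack(
            data=data,
            time_s=time_s,
            pixel_size_um=0.072,
            channel_roles={"damage": 0, "dna": 1},
        )
        masks = np.ones((n, *frames_ch1[0].shape), dtype=int)
        return stack, masks

    def test_identical_channels_give_constant_unity_series(self):
        img = blob_texture((64, 64), 25, 3.0, 3.0, seed=8)
        stack, masks = self._stack_and_masks([img] * 3, [img] * 3)
        df = timelapse_iccs(stack, masks)
        assert len(df) == 3
        assert np.allclose(df["f1"], 1.0, atol=0.05)

    def test_empty_mask_frame_yields_missing_value_only_there(self):
        img = blob_texture((64, 64), 25, 3.0, 3.0, seed=8)
        stack, masks = self._stack_and_masks([img] * 3, [img] * 3)
        masks[1] = 0
        df = timelapse_iccs(stack, masks)
        assert np.isnan(df["f1"].iloc[1]) and not df["valid"].iloc[1]
        assert np.isfinite(df["f1"].iloc[0]) and np.isfinite(df["f1"].iloc[2])

    def test_no_post_bleach_frames_gives_empty_series(self):
        img = blob_texture((64, 64), 25, 3.0, 3.0, seed=8)
        stack, masks = self._stack_and_masks([img] * 3, [img] * 3)
        stack.time_s = stack.time_s - 100.0  # all pre-bleach
        df = timelapse_iccs(stack, masks)
        assert len(df) == 0
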