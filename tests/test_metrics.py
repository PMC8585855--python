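import numpy as np
import pytest

from sliderasl import blur_correlation, gaussian_smooth_slices, gm_mask, \
    match_blur, snr_report, spatial_snr, temporal_snr
from sliderasl.metrics import DegenerateMetricWarning, MetricError


def brute_force_ssnr(frames, mask):
    """Direct transcription of the even/odd sum-difference definition."""
    even = frames[..., 0::2].mean(axis=3)
    odd = frames[..., 1::2].mean(axis=3)
    s = (even + odd)[mask]
    d = (even - odd)[mask]
    return s.mean() / (d.std(ddof=1) / np.sqrt(2.0))


def brute_force_tsnr(frames, mask):
    vox = frames[mask]
    mean = vox.mean(axis=1)
    sd = vox.std(axis=1, ddof=1)
    keep = sd > 0
    return (mean[keep] / sd[keep]).mean()


@pytest.fixture
def noisy_frames():
    rng = np.random.default_rng(31)
    signal = 5.0 + rng.normal(size=(10, 10, 12)) * 0.5
    return signal[..., None] + rng.normal(size=(10, 10, 12, 24))


@pytest.fixture
def full_mask():
    return np.ones((10, 10, 12), dtype=bool)


class TestGmMask:
    def test_threshold_semantics(self):
        assert gm_mask(np.ones((4, 4, 4)), 0.9).all()
        with pytest.raises(MetricError, match="empty"):
            gm_mask(np.full((4, 4, 4), 0.89), 0.9)
        with pytest.raises(MetricError, match=r"\[0, 1\]"):
            gm_mask(np.full((2, 2, 2), 1.2))

    def test_phantom_probability_reproduces_label(self, phantom):
        mask = gm_mask(phantom.gm_probability, 0.9)
        np.testing.assert_array_equal(mask, phantom.labels == 3)


class TestSpatialSNR:
    def test_matches_brute_force(self, noisy_frames, full_mask):
        got = spatial_snr(noisy_frames, full_mask)
        assert got == pytest.approx(brute_force_ssnr(noisy_frames, full_mask),
                                    abs=1e-10)

    def test_scale_invariant_and_homogeneous_in_signal(self, full_mask):
        rng = np.random.default_rng(2)
        noise = rng.normal(size=(10, 10, 12, 20))
        s1 = 4.0 + noise
        # global rescaling cancels exactly; doubling only the signal doubles
        # sSNR up to the noise contribution to the sum image's mean
        assert spatial_snr(5.0 * s1, full_mask) == pytest.approx(
            spatial_snr(s1, full_mask), rel=1e-12)
        assert spatial_snr(8.0 + noise, full_mask) == pytest.approx(
            2 * spatial_snr(s1, full_mask), rel=5e-3)

    def test_scales_with_sqrt_n_frames(self, full_mask):
        """Averaging more frames raises sSNR like sqrt(n)."""
        rng = np.random.default_rng(8)
        base = 3.0 + rng.normal(size=(10, 10, 12, 400))
        r = spatial_snr(base, full_mask) / spatial_snr(base[..., :100],
                                                       full_mask)
        assert r == pytest.approx(2.0, rel=0.25)

    def test_degenerate_and_errors(self, full_mask):
        const = np.ones((10, 10, 12, 4))
        with pytest.warns(DegenerateMetricWarning):
            assert spatial_snr(const, full_mask) == np.inf
        with pytest.raises(MetricError, match="2 perfusion frames"):
            spatial_snr(const[..., :1], full_mask)
        with pytest.raises(MetricError, match="mask"):
            spatial_snr(const, full_mask[:5])


class TestTemporalSNR:
    def test_matches_brute_force(self, noisy_frames, full_mask):
        assert temporal_snr(noisy_frames, full_mask) == pytest.approx(
            brute_force_tsnr(noisy_frames, full_mask), abs=1e-10)

    def test_closed_form_constant_mean(self, full_mask):
        """iid Normal(c, sigma^2) frames give tSNR -> c/sigma."""
        rng = np.random.default_rng(3)
        frames = 7.0 + 2.0 * rng.normal(size=(10, 10, 12, 2000))
        assert temporal_snr(frames, full_mask) == pytest.approx(3.5, rel=0.02)

    def test_scale_invariance(self, noisy_frames, full_mask):
        assert temporal_snr(3.3 * noisy_frames, full_mask) == pytest.approx(
            temporal_snr(noisy_frames, full_mask), rel=1e-12)

    def test_aggregation_modes_differ(self, noisy_frames, full_mask):
        pv = temporal_snr(noisy_frames, full_mask, mode="per_voxel")
        rm = temporal_snr(noisy_frames, full_mask, mode="ratio_of_means")
        assert pv != rm
        with pytest.raises(MetricError, match="mode"):
            temporal_snr(noisy_frames, full_mask, mode="median")

    def test_degenerate_flag(self, full_mask):
        with pytest.warns(DegenerateMetricWarning):
            assert temporal_snr(np.ones((10, 10, 12, 5)), full_mask) == np.inf


class TestBlurCorrelation:
    def test_iid_noise_near_zero(self):
        rng = np.random.default_rng(4)
        assert abs(blur_correlation(rng.normal(size=(20, 20, 40)))) < 0.05

    def test_slice_constant_near_one(self):
        rng = np.random.default_rng(5)
        vol = np.repeat(rng.normal(size=(20, 20, 1)), 30, axis=2)
        assert blur_correlation(vol) == pytest.approx(1.0, abs=1e-9)

    def test_constant_volume_degenerate(self):
        with pytest.warns(DegenerateMetricWarning):
            assert np.isnan(blur_correlation(np.ones((5, 5, 6))))

    def test_mask_policy(self):
        rng = np.random.default_rng(6)
        vol = rng.normal(size=(10, 10, 10))
        mask = np.zeros_like(vol, dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        r_masked = blur_correlation(vol, mask)
        assert -1 <= r_masked <= 1
        with pytest.raises(MetricError, match="overlapping"):
            single = np.zeros_like(mask)
            single[0, 0, 0] = True
            blur_correlation(vol, single)


class TestSmoothingAndMatch:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(7)
        vol = rng.normal(size=(8, 8, 16))
        np.testing.assert_array_equal(gaussian_smooth_slices(vol, 0.0), vol)

    def test_blur_correlation_monotone_in_fwhm(self):
        rng = np.random.default_rng(9)
        vol = rng.normal(size=(16, 16, 48))
        rs = [blur_correlation(gaussian_smooth_slices(vol, f))
              for f in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(b > a - 1e-12 for a, b in zip(rs, rs[1:]))

    def test_match_current_r_returns_zero_fwhm(self):
        rng = np.random.default_rng(10)
        vol = rng.normal(size=(12, 12, 32))
        res = match_blur(vol, blur_correlation(vol))
        assert res.fwhm_voxels == pytest.approx(0.0, abs=1e-6)

    def test_match_blur_agrees_with_grid_search(self):
        """Bisection reproduces a brute-force 0.01-voxel grid search."""
        rng = np.random.default_rng(11)
        vol = rng.normal(size=(16, 16, 48))
        target = 0.6
        res = match_blur(vol, target, tol=1e-4)
        grid = np.arange(0.0, 4.0, 0.01)
        errs = [abs(blur_correlation(gaussian_smooth_slices(vol, f)) - target)
                for f in grid]
        best = grid[int(np.argmin(errs))]
        assert res.fwhm_voxels == pytest.approx(best, abs=0.02)
        assert res.achieved_r == pytest.approx(target, abs=2e-4)

    def test_unreachable_targets_raise(self):
        rng = np.random.default_rng(12)
        vol = rng.normal(size=(10, 10, 24))
        r0 = blur_correlation(vol)
        with pytest.raises(MetricError, match="below"):
            match_blur(vol, r0 - 0.2)
        with pytest.raises(MetricError, match="unreachable"):
            match_blur(vol, 0.9999, fwhm_bounds=(0.0, 0.5))


def test_snr_report_assembles_metrics(noisy_frames, full_mask):
    report = snr_report(noisy_frames, full_mask, condition="demo", lam=0.1)
    assert report.ssnr == pytest.approx(
        brute_force_ssnr(noisy_frames, full_mask), abs=1e-10)
    assert report.mask_voxels == full_mask.sum()
    assert not report.degenerate
    assert report.as_dict()["condition"] == "demo"
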