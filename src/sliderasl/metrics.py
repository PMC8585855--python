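"""Evaluation statistics for reconstructed perfusion images.

Spatial SNR uses the even/odd sum-difference construction: even- and
odd-numbered perfusion frames are averaged, added and subtracted; sSNR is
the mean of the sum image divided by 1/sqrt(2) of the standard deviation of
the difference image within the mask.  Temporal SNR is the per-voxel mean
over SD across frames, averaged in the mask.  Slice blurring is summarised
by the Pearson correlation between the volume and its one-slice-shifted
copy, and can be *matched* across conditions by 1-D Gaussian smoothing
along the slice axis whose FWHM is found by bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .volumes import VolumeSeries, perfusion_frames

__all__ = ["MetricError", "DegenerateMetricWarning", "SNRReport", "gm_mask",
           "spatial_snr", "temporal_snr", "blur_correlation",
           "gaussian_smooth_slices", "match_blur", "MatchBlurResult",
           "snr_report"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class MetricError(ValueError):
    """Metric preconditions violated (empty mask, too few frames, ...)."""


class DegenerateMetricWarning(UserWarning):
    """A metric hit a zero-variance input and returned a sentinel."""


@dataclass
class SNRReport:
    """Quality summary of one reconstruction condition."""

    ssnr: float
    tsnr: float
    blur_corr: float
    mask_voxels: int
    condition: str = ""
    lam: float | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "lambda": self.lam,
            "ssnr": self.ssnr,
            "tsnr": self.tsnr,
            "blur_correlation": self.blur_corr,
            "mask_voxels": self.mask_voxels,
            "degenerate": self.degenerate,
        }


def _frames(perfusion) -> np.ndarray:
    if isinstance(perfusion, VolumeSeries):
        return perfusion_frames(perfusion).data
    arr = np.asarray(perfusion, dtype=float)
    if arr.ndim != 4:
        raise MetricError(f"expected a 4-D series, got {arr.ndim}-D")
    return arr


def gm_mask(probability_map: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Binary mask of voxels with tissue probability >= ``threshold``."""
    prob = np.asarray(probability_map, dtype=float)
    if np.any(prob < 0) or np.any(prob > 1):
        raise MetricError("probabilities must lie in [0, 1]")
    mask = prob >= threshold
    if not mask.any():
        raise MetricError(
            f"empty mask at threshold {threshold}; metrics are undefined")
    return mask


def spatial_snr(perfusion, mask: np.ndarray) -> float:
    """Even/odd sum-difference spatial SNR within ``mask``.

    Returns ``inf`` (with a :class:`DegenerateMetricWarning`) when the
    difference image has zero variance in the mask.
    """
    frames = _frames(perfusion)
    if frames.shape[3] < 2:
        raise MetricError("spatial SNR needs at least 2 perfusion frames")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frames.shape[:3]:
        raise MetricError(
            f"mask shape {mask.shape} does not match volume {frames.shape[:3]}")
    if not mask.any():
        raise MetricError("empty mask")
    even = frames[..., 0::2].mean(axis=3)
    odd = frames[..., 1::2].mean(axis=3)
    total = (even + odd)[mask]
    diff = (even - odd)[mask]
    sd = diff.std(ddof=1) if diff.size > 1 else 0.0
    if sd == 0:
        warnings.warn("zero-variance difference image; spatial SNR is "
                      "degenerate", DegenerateMetricWarning, stacklevel=2)
        return np.inf
    return float(total.mean() / (sd / np.sqrt(2.0)))


def temporal_snr(perfusion, mask: np.ndarray,
                 mode: str = "per_voxel") -> float:
    """Temporal SNR (mean over SD across frames) within ``mask``.

    ``mode='per_voxel'`` averages the per-voxel mean/SD ratio over the mask
    (matching per-voxel tSNR maps); ``mode='ratio_of_means'`` divides the
    mask-mean signal by the mask-mean temporal SD.  Zero-SD voxels are
    excluded; an all-degenerate mask returns ``inf`` with a warning.
    """
    if mode not in ("per_voxel", "ratio_of_means"):
        raise MetricError(f"unknown tSNR mode {mode!r}")
    frames = _frames(perfusion)
    if frames.shape[3] < 2:
        raise MetricError("temporal SNR needs at least 2 frames")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frames.shape[:3]:
        raise MetricError("mask shape does not match volume")
    if not mask.any():
        raise MetricError("empty mask")
    voxels = frames[mask]                    # (n_mask, n_frames)
    mean = voxels.mean(axis=1)
    sd = voxels.std(axis=1, ddof=1)
    ok = sd > 0
    if not ok.any():
        warnings.warn("all mask voxels have zero temporal SD; tSNR is "
                      "degenerate", DegenerateMetricWarning, stacklevel=2)
        return np.inf
    if mode == "per_voxel":
        return float((mean[ok] / sd[ok]).mean())
    return float(mean[ok].mean() / sd[ok].mean())


def blur_correlation(volume: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson r between a volume and its one-slice-shifted copy.

    All voxels of the overlapping slab are collapsed into a vector; an
    optional ``mask`` restricts to voxels inside the mask in *both* shifted
    positions.  A constant volume is degenerate (returns ``nan`` with a
    warning).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 4:
        vol = vol.mean(axis=3)
    if vol.ndim != 3 or vol.shape[2] < 2:
        raise MetricError("blur correlation needs a 3-D volume with >= 2 slices")
    a = vol[:, :, :-1]
    b = vol[:, :, 1:]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.shape:
            raise MetricError("mask shape does not match volume")
        keep = mask[:, :, :-1] & mask[:, :, 1:]
        if not keep.any():
            raise MetricError("mask leaves no overlapping voxels")
        a, b = a[keep], b[keep]
    else:
        a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant volume; blur correlation is undefined",
                      DegenerateMetricWarning, stacklevel=2)
        return np.nan
    return float(pearsonr(a, b).statistic)


def gaussian_smooth_slices(volume: np.ndarray, fwhm_voxels: float) -> np.ndarray:
    """1-D Gaussian smoothing along the slice axis (axis 2), reflect edges.

    ``fwhm_voxels = 0`` returns the input unchanged (copied).  Works on 3-D
    volumes and 4-D series (each frame smoothed identically).
    """
    vol = np.asarray(volume, dtype=float)
    if fwhm_voxels < 0:
        raise MetricError("FWHM must be >= 0")
    if fwhm_voxels == 0:
        return vol.copy()
    sigma = fwhm_voxels * FWHM_TO_SIGMA
    return gaussian_filter1d(vol, sigma, axis=2, mode="reflect")


@dataclass
class MatchBlurResult:
    fwhm_voxels: float
    volume: np.ndarray
    achieved_r: float


def match_blur(
    volume: np.ndarray,
    target_r: float,
    fwhm_bounds: tuple[float, float] = (0.0, 8.0),
    tol: float = 1e-3,
    max_iter: int = 100,
) -> MatchBlurResult:
    """Find the slice-axis Gaussian FWHM whose blur correlation hits
    ``target_r``.

    ``blur_correlation`` is monotone non-decreasing in the FWHM, so the
    match is found by bisection to within ``tol`` in r.  Raises
    :class:`MetricError` when the target lies below the unsmoothed
    correlation or above what the upper bound can reach.
    """
    vol = np.asarray(volume, dtype=float)
    lo, hi = fwhm_bounds
    if lo < 0 or hi <= lo:
        raise MetricError(f"invalid FWHM bounds {fwhm_bounds}")
    r_lo = blur_correlation(gaussian_smooth_slices(vol, lo))
    if target_r <= r_lo + tol:
        if target_r < r_lo - tol:
            raise MetricError(
                f"target r={target_r:.4f} below the unsmoothed correlation "
                f"{r_lo:.4f}; smoothing can only increase it")
        return MatchBlurResult(lo, gaussian_smooth_slices(vol, lo), r_lo)
    r_hi = blur_correlation(gaussian_smooth_slices(vol, hi))
    if target_r > r_hi + tol:
        raise MetricError(
            f"target r={target_r:.4f} unreachable within FWHM <= {hi} "
            f"(max r={r_hi:.4f})")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = blur_correlation(gaussian_smooth_slices(vol, mid))
        if abs(r_mid - target_r) <= tol:
            return MatchBlurResult(mid, gaussian_smooth_slices(vol, mid), r_mid)
        if r_mid < target_r:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    smoothed = gaussian_smooth_slices(vol, mid)
    return MatchBlurResult(mid, smoothed, blur_correlation(smoothed))


def snr_report(perfusion, mask: np.ndarray, condition: str = "",
               lam: float | None = None) -> SNRReport:
    """Assemble spatial/temporal SNR and blur correlation for one condition."""
    frames = _frames(perfusion)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DegenerateMetricWarning)
        ssnr = spatial_snr(frames, mask)
        tsnr = temporal_snr(frames, mask)
        blur = blur_correlation(frames.mean(axis=3))
        degenerate = any(issubclass(w.category, DegenerateMetricWarning)
                         for w in caught)
    return SNRReport(ssnr=ssnr, tsnr=tsnr, blur_corr=blur,
                     mask_voxels=int(np.asarray(mask, bool).sum()),
                     condition=condition, lam=lam, degenerate=degenerate)
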