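"""Cerebral blood flow quantification with slice-dependent PLD correction.

Single-compartment (general kinetic) model for continuous/pseudo-continuous
labeling:

    CBF = 6000 * lambda_p * dM * exp(PLD_i / T1b)
          / (2 * alpha * T1b_s * M0 * (1 - exp(-tau / T1b)))      [ml/100g/min]

where ``dM`` is the control-label difference, ``M0`` the equilibrium
magnetisation, ``tau`` the labeling duration, ``T1b`` the longitudinal
relaxation time of arterial blood (``T1b_s`` in seconds) and ``PLD_i`` the
post-labeling delay of slice ``i``: the nominal PLD plus the readout offset
of the slice group the slice was acquired in (2-D multi-slice readouts image
later groups at longer delays, which the correction removes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CBFParams", "CBFResult", "signal_scale", "quantify_cbf",
           "roi_means"]


@dataclass(frozen=True)
class CBFParams:
    """Quantification constants (consensus single-compartment defaults)."""

    labeling_efficiency: float = 0.85
    blood_t1_ms: float = 1650.0
    partition_coefficient: float = 0.9  # ml/g
    label_duration_ms: float = 1500.0
    pld_ms: float = 1800.0

    def __post_init__(self) -> None:
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling efficiency must be in (0, 1]")
        if self.blood_t1_ms <= 0:
            raise ValueError("blood T1 must be positive")
        if self.partition_coefficient <= 0:
            raise ValueError("partition coefficient must be positive")
        if self.label_duration_ms <= 0 or self.pld_ms < 0:
            raise ValueError("invalid labeling timing")

    def as_dict(self) -> dict:
        return {
            "labeling_efficiency": self.labeling_efficiency,
            "blood_t1_ms": self.blood_t1_ms,
            "partition_coefficient": self.partition_coefficient,
            "label_duration_ms": self.label_duration_ms,
            "pld_ms": self.pld_ms,
        }


def signal_scale(params: CBFParams, pld_ms: float | np.ndarray) -> np.ndarray:
    """Difference-signal per unit ``M0 * CBF`` at delay ``pld_ms``.

    The model's forward direction: ``dM = signal_scale * M0 * CBF`` with CBF
    in ml/100 g/min.  Used by the simulator so that quantification inverts
    the simulated signal exactly.
    """
    t1b_s = params.blood_t1_ms / 1000.0
    tau_factor = 1.0 - np.exp(-params.label_duration_ms / params.blood_t1_ms)
    decay = np.exp(-np.asarray(pld_ms, dtype=float) / params.blood_t1_ms)
    return (2.0 * params.labeling_efficiency * t1b_s * tau_factor * decay
            / (6000.0 * params.partition_coefficient))


@dataclass
class CBFResult:
    """CBF map with the validity mask used during quantification."""

    cbf: np.ndarray        # ml/100 g/min; NaN outside the mask
    mask: np.ndarray       # voxels with usable M0
    n_masked: int          # voxels excluded for non-positive/low M0
    params: CBFParams
    m0_threshold: float


def quantify_cbf(
    perfusion_mean: np.ndarray,
    m0: np.ndarray,
    params: CBFParams = CBFParams(),
    slice_offsets_ms: np.ndarray | None = None,
    m0_threshold: float | None = None,
) -> CBFResult:
    """Convert a mean perfusion-difference volume and M0 into CBF.

    ``slice_offsets_ms`` gives the per-slice readout offset added to the
    nominal PLD (from :func:`sliderasl.geometry.hr_slice_timing`); ``None``
    applies no slice-dependent correction.  Voxels with M0 at or below
    ``m0_threshold`` (default: 10 % of the robust M0 maximum, the 99th
    percentile) are masked out, counted and set to NaN.
    """
    dm = np.asarray(perfusion_mean, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if dm.shape != m0.shape:
        raise ValueError(
            f"perfusion {dm.shape} and M0 {m0.shape} shapes differ")
    if slice_offsets_ms is None:
        offsets = np.zeros(dm.shape[2])
    else:
        offsets = np.asarray(slice_offsets_ms, dtype=float)
        if offsets.shape != (dm.shape[2],):
            raise ValueError(
                f"need one offset per slice ({dm.shape[2]}), got {offsets.shape}")
    if m0_threshold is None:
        robust_max = float(np.percentile(m0, 99))
        m0_threshold = 0.1 * robust_max
    mask = m0 > m0_threshold
    pld = params.pld_ms + offsets
    scale = signal_scale(params, pld)[np.newaxis, np.newaxis, :]
    cbf = np.full(dm.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = dm / (scale * m0)
    cbf[mask] = full[mask]
    return CBFResult(cbf=cbf, mask=mask, n_masked=int((~mask).sum()),
                     params=params, m0_threshold=float(m0_threshold))


def roi_means(
    cbf_map: np.ndarray,
    roi_labels: np.ndarray,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Mean CBF per labelled region.

    ``roi_labels`` is an integer volume aligned with ``cbf_map``; label 0 is
    background and skipped.  NaN voxels (masked during quantification) are
    excluded from the means; an ROI with no valid voxels is flagged empty.
    """
    cbf_map = np.asarray(cbf_map, dtype=float)
    roi_labels = np.asarray(roi_labels)
    if cbf_map.shape != roi_labels.shape:
        raise ValueError(
            f"CBF {cbf_map.shape} and label {roi_labels.shape} shapes differ")
    rows = []
    for label in np.unique(roi_labels):
        if label == 0:
            continue
        values = cbf_map[roi_labels == label]
        valid = values[np.isfinite(values)]
        rows.append({
            "roi": int(label),
            "name": (names or {}).get(int(label), str(int(label))),
            "n_voxels": int(values.size),
            "n_valid": int(valid.size),
            "mean_cbf": float(valid.mean()) if valid.size else np.nan,
            "empty": valid.size == 0,
        })
    return pd.DataFrame(rows)
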