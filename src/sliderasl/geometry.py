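"""Acquisition geometry for slice-dithered (SLIDER) SMS ASL protocols.

A SLIDER acquisition repeats a thick-slice simultaneous-multi-slice (SMS)
stack ``n_set`` times, shifting the whole slab by one thin-slice width
between repeats.  The thick slices are ``n_set`` thin slices wide, so the
shifted stacks jointly sample a thin-slice grid that super-resolution
reconstruction can recover.  This module holds the protocol arithmetic:
slice counts, coverage, band placement and slice-group timing.

Slice convention: slice index 0 is the most inferior slice; positions are
thin-slice-centre millimetres in the half-open slab ``[0, coverage)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "GeometryError",
    "HRGrid",
    "PRESETS",
    "build_geometry",
    "hr_grid",
    "slice_group_timing",
    "hr_slice_timing",
]


class GeometryError(ValueError):
    """A protocol configuration violates a geometry invariant."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Validated SLIDER-SMS protocol description.

    Parameters
    ----------
    n_set:
        Number of shifted thick-slice acquisitions.  ``n_set == 1`` denotes
        the thin-slice protocol (thick == thin); combined with
        ``reference_passes == 2`` it is the interleaved two-pass reference.
    thin_thickness_mm:
        Target (reconstructed) slice thickness; also the per-set shift step.
    thick_thickness_mm:
        Acquired slice thickness, ``n_set * thin_thickness_mm``.
    mb_factor, n_groups:
        Simultaneously excited slices per shot and number of sequentially
        excited slice groups; ``mb_factor * n_groups`` thick slices per TR.
    band_spacing_mm:
        Edge-to-edge gap between adjacent simultaneous bands,
        ``(n_groups - 1) * thick_thickness_mm`` (20/30/40 mm for 4/6/8 mm
        slices with six groups).  ``None`` skips the check (gapped reference).
    group_readout_ms, tr_ms, label_duration_ms, pld_ms:
        Sequence timing.  ``pld_ms`` is the nominal post-labeling delay of
        the first slice group; later groups add ``group_readout_ms`` each.
    reference_passes:
        1 for SLIDER protocols; 2 for the interleaved thin-slice reference
        (even slices in pass 0, odd slices in pass 1, 100 % gap per pass).
    shift_sign:
        Direction of the per-set slab shift in slice-index units (+1: the
        thick-slice footprint of set ``k`` starts ``k`` thin slices higher).
    """

    n_set: int
    thin_thickness_mm: float
    thick_thickness_mm: float
    mb_factor: int
    n_groups: int
    band_spacing_mm: float | None = None
    group_readout_ms: float = 45.0
    tr_ms: float = 5000.0
    label_duration_ms: float = 1500.0
    pld_ms: float = 1800.0
    reference_passes: int = 1
    shift_sign: int = 1
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for attr in ("n_set", "mb_factor", "n_groups", "reference_passes"):
            v = getattr(self, attr)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise GeometryError(f"{attr} must be a positive integer, got {v!r}")
        for attr in ("thin_thickness_mm", "thick_thickness_mm",
                     "group_readout_ms", "tr_ms"):
            if getattr(self, attr) <= 0:
                raise GeometryError(f"{attr} must be positive")
        if self.shift_sign not in (-1, 1):
            raise GeometryError("shift_sign must be +1 or -1")
        expected_thick = self.n_set * self.thin_thickness_mm
        if not np.isclose(self.thick_thickness_mm, expected_thick):
            raise GeometryError(
                "violated invariant thick_thickness_mm == n_set * thin_thickness_mm: "
                f"{self.thick_thickness_mm} != {self.n_set} * {self.thin_thickness_mm}"
            )
        if self.band_spacing_mm is not None:
            expected_gap = (self.n_groups - 1) * self.thick_thickness_mm
            if not np.isclose(self.band_spacing_mm, expected_gap):
                raise GeometryError(
                    "violated invariant band_spacing_mm == "
                    "(n_groups - 1) * thick_thickness_mm: "
                    f"{self.band_spacing_mm} != {expected_gap}"
                )
        if self.reference_passes > 1 and self.n_set != 1:
            raise GeometryError("interleaved passes require n_set == 1")

    # -- derived quantities -------------------------------------------------

    @property
    def n_thick_slices(self) -> int:
        """Thick slices acquired per TR (mb_factor x n_groups)."""
        return self.mb_factor * self.n_groups

    @property
    def shift_step_mm(self) -> float:
        """Per-set slab shift; one thin slice by construction."""
        return self.thin_thickness_mm

    @property
    def total_readout_ms(self) -> float:
        return self.n_groups * self.group_readout_ms

    @property
    def is_reference(self) -> bool:
        return self.reference_passes > 1


@dataclass(frozen=True)
class HRGrid:
    """Thin-slice reconstruction grid derived from a geometry."""

    n_slices: int
    spacing_mm: float
    coverage_mm: float
    positions_mm: np.ndarray  # thin-slice centres, most inferior first


#: Protocols used throughout: three SLIDER variants plus the interleaved
#: two-pass thin-slice reference, all 24 thick slices per TR, TR 5 s,
#: 1500 ms labeling, 1800 ms PLD, 45 ms per slice group.
PRESETS: dict[str, dict] = {
    "reference": dict(n_set=1, thin_thickness_mm=2.0, mb_factor=4, n_groups=6,
                      reference_passes=2),
    "slider2": dict(n_set=2, thin_thickness_mm=2.0, mb_factor=4, n_groups=6,
                    band_spacing_mm=20.0),
    "slider3": dict(n_set=3, thin_thickness_mm=2.0, mb_factor=4, n_groups=6,
                    band_spacing_mm=30.0),
    "slider4": dict(n_set=4, thin_thickness_mm=2.0, mb_factor=4, n_groups=6,
                    band_spacing_mm=40.0),
}


def build_geometry(config: str | Mapping) -> AcquisitionGeometry:
    """Build a validated :class:`AcquisitionGeometry`.

    ``config`` is a preset name (``reference``/``slider2``/``slider3``/
    ``slider4``), or a mapping of field values.  A mapping may name a
    ``preset`` to start from and override individual fields.
    ``thick_thickness_mm`` may be omitted and is derived as
    ``n_set * thin_thickness_mm``.
    """
    if isinstance(config, str):
        name = config
        if name not in PRESETS:
            raise GeometryError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        params = dict(PRESETS[name])
    else:
        params = dict(config)
        name = params.pop("preset", "")
        if name:
            if name not in PRESETS:
                raise GeometryError(
                    f"unknown preset {name!r}; available: {sorted(PRESETS)}")
            base = dict(PRESETS[name])
            base.update(params)
            params = base
    params.setdefault("name", name)
    if "thick_thickness_mm" not in params:
        params["thick_thickness_mm"] = (
            params["n_set"] * params["thin_thickness_mm"])
    return AcquisitionGeometry(**params)


def hr_grid(geometry: AcquisitionGeometry) -> HRGrid:
    """Thin-slice grid of the reconstruction.

    SLIDER protocols divide the nominal unshifted slab
    (``n_thick_slices * thick_thickness_mm``) into
    ``n_thick_slices * n_set`` thin slices.  The two-pass reference covers
    ``n_thick_slices * reference_passes`` thin slices (the interleaved
    even/odd stacks form one gap-free grid).
    """
    n = geometry.n_thick_slices * geometry.n_set * geometry.reference_passes
    d = geometry.thin_thickness_mm
    return HRGrid(
        n_slices=n,
        spacing_mm=d,
        coverage_mm=n * d,
        positions_mm=(np.arange(n) + 0.5) * d,
    )


def slice_group_timing(geometry: AcquisitionGeometry) -> np.ndarray:
    """Acquisition-time offset (ms) of every thick slice within one TR.

    Thick slice ``t`` belongs to slice group ``t % n_groups`` (interleaved
    SMS bands, ``n_groups`` slices apart); group ``g`` is read out at
    ``g * group_readout_ms``.
    """
    t = np.arange(geometry.n_thick_slices)
    return (t % geometry.n_groups) * geometry.group_readout_ms


def hr_slice_timing(geometry: AcquisitionGeometry) -> np.ndarray:
    """Acquisition-time offset (ms) inherited by every thin slice.

    A thin slice reconstructed from a SLIDER acquisition inherits the
    readout offset of the unshifted (set 0) thick slice containing it.
    For the two-pass reference, thin slice ``j`` was acquired as slice
    ``j // 2`` of pass ``j % 2``.
    """
    grid = hr_grid(geometry)
    group_offsets = slice_group_timing(geometry)
    j = np.arange(grid.n_slices)
    if geometry.is_reference:
        t = j // geometry.reference_passes
    else:
        t = np.minimum(j // geometry.n_set, geometry.n_thick_slices - 1)
    return group_offsets[t]


def with_overrides(geometry: AcquisitionGeometry, **kwargs) -> AcquisitionGeometry:
    """Return a copy of ``geometry`` with fields replaced (re-validated)."""
    return replace(geometry, **kwargs)
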