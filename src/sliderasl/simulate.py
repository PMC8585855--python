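"""Digital-phantom acquisition simulator for SLIDER-SMS ASL.

Generates a brain-like tissue phantom on the thin-slice grid and synthesises
thick-slice shifted acquisitions (and the interleaved thin-slice reference)
with the noise structure the SNR-efficiency model assumes:

* thermal noise, independent across frames, amplified by a per-voxel
  g-factor map;
* physiological noise as an AR(1) process over label/control pairs with
  marginal variance ``var_physio`` and lag-1 correlation ``rho``, added in
  image space after thick-slice projection (it is a property of the
  acquired measurement) and not amplified by g;
* label/control pairs whose difference carries the perfusion signal.

Noise calibration.  ``var_thermal`` is the thermal variance of one
perfusion-difference image at *thin-slice* signal calibration.  Raw coil
noise per acquired image is independent of slice thickness while signal
grows with it, so in the averaging (mean) signal convention a thick-slice
acquisition has thermal sd reduced by thin/thick = 1/n_set.  The simulator
applies that factor internally: the thick-slice SNR advantage that drives
super-resolution SNR efficiency lives entirely in the noise bookkeeping,
with signal units preserved across resolutions.  Each frame of a pair takes
half the difference-image variance; physiological noise is split +-p/2
across the pair so the difference carries exactly ``var_physio``.

The perfusion difference signal is generated by inverting the
single-compartment quantification model, ``dM = k(PLD_slice) * M0 * CBF``,
with the slice-dependent PLD of the (set 0) slice group containing each
thin slice, so simulate -> reconstruct -> quantify is exactly
self-consistent.  Resulting grey-matter dM/M0 is ~0.6 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import zoom

from .forward import ForwardOperator, build_forward_operator
from .geometry import AcquisitionGeometry, hr_grid, hr_slice_timing
from .quant import CBFParams, signal_scale
from .volumes import CONTROL, LABEL, M0, VolumeSeries

__all__ = ["Phantom", "NoiseModel", "SimulationResult", "ReferenceSimulation",
           "make_phantom", "simulate_acquisition", "simulate_reference",
           "TISSUE_BACKGROUND", "TISSUE_CSF", "TISSUE_WM", "TISSUE_GM"]

TISSUE_BACKGROUND = 0
TISSUE_CSF = 1
TISSUE_WM = 2
TISSUE_GM = 3

#: Perfusion in ml/100 g/min and M0 in arbitrary units per tissue class.
DEFAULT_PERFUSION = {TISSUE_GM: 60.0, TISSUE_WM: 20.0, TISSUE_CSF: 0.0,
                     TISSUE_BACKGROUND: 0.0}
DEFAULT_M0 = {TISSUE_GM: 1000.0, TISSUE_WM: 700.0, TISSUE_CSF: 1300.0,
              TISSUE_BACKGROUND: 0.0}


@dataclass
class Phantom:
    """Tissue-label volume on the thin-slice grid with per-tissue values."""

    labels: np.ndarray                  # (nx, ny, nz) uint8 tissue codes
    perfusion: dict[int, float]         # ml/100 g/min per tissue
    m0: dict[int, float]                # arbitrary units per tissue
    spacing: tuple[float, float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("phantom labels must be a 3-D volume")
        if any(v < 0 for v in self.perfusion.values()):
            raise ValueError("perfusion values must be >= 0")
        if self.perfusion.get(TISSUE_BACKGROUND, 0.0) != 0.0:
            raise ValueError("background perfusion must be 0")

    def _value_map(self, table: dict[int, float]) -> np.ndarray:
        out = np.zeros(self.labels.shape)
        for code, value in table.items():
            out[self.labels == code] = value
        return out

    @property
    def perfusion_map(self) -> np.ndarray:
        return self._value_map(self.perfusion)

    @property
    def m0_map(self) -> np.ndarray:
        return self._value_map(self.m0)

    @property
    def gm_probability(self) -> np.ndarray:
        """Binary GM probability (1 inside the GM label, 0 elsewhere)."""
        return (self.labels == TISSUE_GM).astype(float)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != TISSUE_BACKGROUND


@dataclass(frozen=True)
class NoiseModel:
    """Thermal + AR(1) physiological noise of one acquisition condition.

    ``var_thermal``: thermal variance of one perfusion-difference image at
    thin-slice calibration (see module docstring).  ``var_physio``/``rho``:
    marginal variance and lag-1 correlation of the physiological AR(1)
    process over pairs.  ``g_map``: noise amplification (scalar or per-voxel
    in-plane map), >= 1, applied to the thermal term only.
    """

    var_thermal: float = 100.0
    var_physio: float = 20.0
    rho: float = 0.5
    g_map: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.var_thermal < 0 or self.var_physio < 0:
            raise ValueError("noise variances must be >= 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if np.any(np.asarray(self.g_map) < 1):
            raise ValueError("g-factor must be >= 1")

    def g_array(self, shape_xy: tuple[int, int]) -> np.ndarray:
        g = np.asarray(self.g_map, dtype=float)
        if g.ndim == 0:
            return np.full(shape_xy, float(g))
        if g.shape != shape_xy:
            raise ValueError(
                f"g map shape {g.shape} does not match in-plane {shape_xy}")
        return g


def make_phantom(
    shape: tuple[int, int, int] = (48, 48, 96),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    perfusion: dict[int, float] | None = None,
    m0: dict[int, float] | None = None,
    seed: int = 0,
) -> Phantom:
    """Brain-like nested-ellipsoid phantom with seeded smooth irregularity.

    Concentric shells (CSF core standing in for the ventricles, WM, a GM
    rim) inside a head-sized ellipsoid, with a smooth random modulation of
    the shell radius so tissue boundaries cut obliquely across many thin
    slices - the situation in which super-resolution is informative.
    Deterministic for a given ``seed``.
    """
    if len(shape) != 3 or min(shape[:2]) < 16 or shape[2] < 8:
        raise ValueError(f"degenerate phantom shape {shape}")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    x = (np.arange(nx) - (nx - 1) / 2) / (nx / 2)
    y = (np.arange(ny) - (ny - 1) / 2) / (ny / 2)
    z = (np.arange(nz) - (nz - 1) / 2) / (nz / 2)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    r = np.sqrt((X / 0.88) ** 2 + (Y / 0.88) ** 2 + (Z / 0.94) ** 2)

    # smooth seeded radial modulation (~6 % of the radius) so that the
    # shell boundaries are not axis-aligned planes
    coarse = rng.normal(0.0, 1.0, size=(4, 4, 6))
    bumps = zoom(coarse, (nx / 4, ny / 4, nz / 6), order=3)[:nx, :ny, :nz]
    bumps = 0.06 * bumps / max(np.abs(bumps).max(), 1e-12)
    r = r * (1.0 + bumps)

    labels = np.full(shape, TISSUE_BACKGROUND, dtype=np.uint8)
    labels[r < 1.0] = TISSUE_GM
    labels[r < 0.72] = TISSUE_WM
    labels[r < 0.30] = TISSUE_CSF
    return Phantom(
        labels=labels,
        perfusion=dict(perfusion or DEFAULT_PERFUSION),
        m0=dict(m0 or DEFAULT_M0),
        spacing=tuple(spacing),
        seed=seed,
    )


@dataclass
class SimulationResult:
    """Thick-slice label/control series per shift set plus ground truth."""

    lr_sets: list[VolumeSeries]
    m0_sets: list[VolumeSeries]
    truth_perfusion: np.ndarray   # noise-free thin-slice dM on the slab
    truth_m0: np.ndarray          # noise-free thin-slice M0 on the slab
    truth_cbf: np.ndarray         # thin-slice CBF on the slab
    slab_start: int               # slab offset on the phantom thin grid
    operator: ForwardOperator | None
    geometry: AcquisitionGeometry
    cbf_params: CBFParams
    seed: int = 0
    meta: dict = field(default_factory=dict)


@dataclass
class ReferenceSimulation:
    """Two interleaved thin-slice passes (even slices, then odd slices)."""

    passes: list[VolumeSeries]
    m0_passes: list[VolumeSeries]
    truth_perfusion: np.ndarray
    truth_m0: np.ndarray
    truth_cbf: np.ndarray
    slab_start: int
    geometry: AcquisitionGeometry
    cbf_params: CBFParams
    seed: int = 0

    def merged(self) -> VolumeSeries:
        from .recon import merge_interleaved

        return merge_interleaved(self.passes[0], self.passes[1])

    def merged_m0(self) -> VolumeSeries:
        from .recon import merge_interleaved

        return merge_interleaved(self.m0_passes[0], self.m0_passes[1])


def _slab(phantom: Phantom, n_hr: int) -> int:
    nz = phantom.labels.shape[2]
    if nz < n_hr:
        raise ValueError(
            f"phantom has {nz} thin slices but the protocol needs {n_hr}")
    # acquisitions of different coverage share a common centre
    return (nz - n_hr) // 2

def _thin_truth(phantom: Phantom, geometry: AcquisitionGeometry,
                cbf_params: CBFParams, slab: int, n_hr: int):
    """Noise-free thin-slice M0, CBF and dM (with slice-dependent PLD)."""
    sl = slice(slab, slab + n_hr)
    m0 = phantom.m0_map[:, :, sl]
    cbf = phantom.perfusion_map[:, :, sl]
    pld = cbf_params.pld_ms + hr_slice_timing(geometry)
    dm = signal_scale(cbf_params, pld)[np.newaxis, np.newaxis, :] * m0 * cbf
    return m0, cbf, dm


def _ar1(rng: np.random.Generator, shape_space: tuple, n: int,
         var: float, rho: float) -> np.ndarray:
    """AR(1) series over the last axis with marginal ``var`` and lag-1 rho."""
    out = np.empty(shape_space + (n,))
    if var == 0:
        out[:] = 0.0
        return out
    sd = np.sqrt(var)
    out[..., 0] = rng.normal(0.0, sd, shape_space)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        out[..., t] = rho * out[..., t - 1] + rng.normal(
            0.0, innov_sd, shape_space)
    return out


def _acquire_series(
    rng: np.random.Generator,
    control_clean: np.ndarray,   # (nx, ny, ns) noise-free control image
    label_clean: np.ndarray,
    noise: NoiseModel,
    n_meas: int,
    thermal_scale: float,        # thin/thick thickness ratio
) -> np.ndarray:
    """Label/control frames (label first) with the full noise model."""
    nx, ny, ns = control_clean.shape
    g = noise.g_array((nx, ny))[:, :, np.newaxis, np.newaxis]
    frames = np.empty((nx, ny, ns, 2 * n_meas))
    frame_sd = np.sqrt(noise.var_thermal / 2.0) * thermal_scale
    thermal = rng.normal(0.0, 1.0, (nx, ny, ns, 2 * n_meas)) * (g * frame_sd)
    physio = _ar1(rng, (nx, ny, ns), n_meas, noise.var_physio, noise.rho)
    frames[..., 0::2] = label_clean[..., np.newaxis] \
        + thermal[..., 0::2] - physio / 2.0
    frames[..., 1::2] = control_clean[..., np.newaxis] \
        + thermal[..., 1::2] + physio / 2.0
    return frames


def simulate_acquisition(
    phantom: Phantom,
    geometry: AcquisitionGeometry,
    noise: NoiseModel = NoiseModel(),
    n_meas: int = 20,
    seed: int = 0,
    operator: ForwardOperator | None = None,
    cbf_params: CBFParams | None = None,
) -> SimulationResult:
    """Simulate the shifted thick-slice SLIDER acquisition.

    Returns one label/control series per shift set (``n_meas`` pairs each,
    label frame first within a pair) plus a noisy single-frame M0 series per
    set.  Protocols with fewer thin slices than the phantom acquire the
    centred sub-slab.  Deterministic for a given ``seed``.
    """
    if n_meas < 1:
        raise ValueError("n_meas must be >= 1")
    if geometry.is_reference:
        raise ValueError("use simulate_reference for the two-pass protocol")
    if operator is None:
        operator = build_forward_operator(geometry)
    if cbf_params is None:
        cbf_params = CBFParams(label_duration_ms=geometry.label_duration_ms,
                               pld_ms=geometry.pld_ms)
    n_hr = hr_grid(geometry).n_slices
    slab = _slab(phantom, n_hr)
    m0_hr, cbf_hr, dm_hr = _thin_truth(phantom, geometry, cbf_params, slab, n_hr)
    thermal_scale = geometry.thin_thickness_mm / geometry.thick_thickness_mm
    rng = np.random.default_rng(seed)
    spacing = (phantom.spacing[0], phantom.spacing[1],
               geometry.thick_thickness_mm)

    lr_sets: list[VolumeSeries] = []
    m0_sets: list[VolumeSeries] = []
    for k in range(geometry.n_set):
        control_k = operator.project(m0_hr, set_index=k)
        label_k = operator.project(m0_hr - dm_hr, set_index=k)
        frames = _acquire_series(rng, control_k, label_k, noise, n_meas,
                                 thermal_scale)
        meta = {"set_index": k, "hr_slab_start": slab,
                "condition": geometry.name or "custom"}
        lr_sets.append(VolumeSeries(
            data=frames, frame_labels=(LABEL, CONTROL) * n_meas,
            spacing=spacing, slab_start=slab, meta=meta))
        g = noise.g_array(m0_hr.shape[:2])[:, :, np.newaxis]
        m0_noisy = control_k + rng.normal(0.0, 1.0, control_k.shape) * (
            g * np.sqrt(noise.var_thermal / 2.0) * thermal_scale)
        m0_sets.append(VolumeSeries(
            data=m0_noisy[..., np.newaxis], frame_labels=(M0,),
            spacing=spacing, slab_start=slab, meta=dict(meta)))
    return SimulationResult(
        lr_sets=lr_sets, m0_sets=m0_sets, truth_perfusion=dm_hr,
        truth_m0=m0_hr, truth_cbf=cbf_hr, slab_start=slab, operator=operator,
        geometry=geometry, cbf_params=cbf_params, seed=seed,
        meta={"n_meas": n_meas})


def simulate_reference(
    phantom: Phantom,
    geometry: AcquisitionGeometry,
    noise: NoiseModel = NoiseModel(),
    n_meas: int = 20,
    seed: int = 0,
    cbf_params: CBFParams | None = None,
) -> ReferenceSimulation:
    """Simulate the two interleaved gapped thin-slice reference scans.

    Pass 0 acquires the even thin slices of the slab, pass 1 the odd ones;
    each pass runs ``n_meas`` label/control pairs under the same noise model
    (thin slices: no thermal thickness scaling).  The merged series covers
    the full thin grid.
    """
    if not geometry.is_reference:
        raise ValueError("geometry is not the two-pass reference protocol")
    if cbf_params is None:
        cbf_params = CBFParams(label_duration_ms=geometry.label_duration_ms,
                               pld_ms=geometry.pld_ms)
    n_hr = hr_grid(geometry).n_slices
    slab = _slab(phantom, n_hr)
    m0_hr, cbf_hr, dm_hr = _thin_truth(phantom, geometry, cbf_params, slab, n_hr)
    rng = np.random.default_rng(seed)
    # each gapped pass acquires thin slices at twice the thin pitch
    spacing = (phantom.spacing[0], phantom.spacing[1],
               geometry.thin_thickness_mm * geometry.reference_passes)

    passes: list[VolumeSeries] = []
    m0_passes: list[VolumeSeries] = []
    for p in range(geometry.reference_passes):
        sl = slice(p, None, geometry.reference_passes)
        control_p = m0_hr[:, :, sl]
        label_p = (m0_hr - dm_hr)[:, :, sl]
        frames = _acquire_series(rng, control_p, label_p, noise, n_meas,
                                 thermal_scale=1.0)
        meta = {"pass_index": p, "hr_slab_start": slab,
                "condition": geometry.name or "reference"}
        passes.append(VolumeSeries(
            data=frames, frame_labels=(LABEL, CONTROL) * n_meas,
            spacing=spacing, slab_start=slab, meta=meta))
        g = noise.g_array(m0_hr.shape[:2])[:, :, np.newaxis]
        m0_noisy = control_p + rng.normal(0.0, 1.0, control_p.shape) * (
            g * np.sqrt(noise.var_thermal / 2.0))
        m0_passes.append(VolumeSeries(
            data=m0_noisy[..., np.newaxis], frame_labels=(M0,),
            spacing=spacing, slab_start=slab, meta=dict(meta)))
    return ReferenceSimulation(
        passes=passes, m0_passes=m0_passes, truth_perfusion=dm_hr,
        truth_m0=m0_hr, truth_cbf=cbf_hr, slab_start=slab, geometry=geometry,
        cbf_params=cbf_params, seed=seed)
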