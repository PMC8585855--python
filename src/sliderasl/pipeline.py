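"""End-to-end pipeline: simulate -> reconstruct -> metrics -> quantify.

Each stage draws its randomness from a seed spawned deterministically from
the master seed, records every file it writes in the run manifest, and
aborts with the stage name on error.  Re-running a manifest's config and
seed reproduces the outputs exactly.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .forward import build_forward_operator
from .geometry import build_geometry, hr_slice_timing
from .io import RunManifest, save_json, write_volume_series
from .metrics import gm_mask, snr_report
from .quant import CBFParams, quantify_cbf, roi_means
from .recon import ReconConfig, merge_interleaved, reconstruct_series
from .simulate import NoiseModel, make_phantom, simulate_acquisition, \
    simulate_reference
from .volumes import VolumeSeries, perfusion_frames

__all__ = ["run_pipeline", "PipelineError", "DEFAULT_CONFIG"]

log = logging.getLogger("sliderasl")

DEFAULT_CONFIG: dict = {
    "presets": ["slider2", "slider4", "reference"],
    "n_meas": 20,
    "lambda": 0.1,
    "phantom": {"shape": [32, 32, 96], "seed": 0},
    "noise": {"var_thermal": 100.0, "var_physio": 20.0, "rho": 0.5, "g": 1.0},
    "quantify": True,
    "write_volumes": True,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str, manifest: RunManifest):
    class _Timer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest.timings_s[name] = round(dt, 3)
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2f s", name, dt)

    return _Timer()


def run_pipeline(config: dict | None, seed: int, out_dir: str | Path) -> RunManifest:
    """Run the demonstration pipeline and return its manifest.

    ``config`` follows :data:`DEFAULT_CONFIG`; missing keys take defaults.
    Writes per-condition simulated volumes, reconstructed thin-slice
    perfusion and M0, an SNR report, and (optionally) CBF maps with tissue
    ROI means, plus ``manifest.json``, under ``out_dir``.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(seed), version=__version__)

    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(
                       ("phantom", *cfg["presets"]), ss.spawn(1 + len(cfg["presets"])))}
    manifest.stage_seeds = stage_seeds

    with _stage("phantom", manifest):
        ph_cfg = cfg["phantom"]
        phantom = make_phantom(shape=tuple(ph_cfg.get("shape", (32, 32, 96))),
                               seed=int(ph_cfg.get("seed", 0)))
    noise_cfg = cfg["noise"]
    noise = NoiseModel(var_thermal=noise_cfg.get("var_thermal", 100.0),
                       var_physio=noise_cfg.get("var_physio", 20.0),
                       rho=noise_cfg.get("rho", 0.5),
                       g_map=noise_cfg.get("g", 1.0))
    lam = float(cfg["lambda"])
    n_meas = int(cfg["n_meas"])
    reports = []

    for preset in cfg["presets"]:
        geometry = build_geometry(preset)
        cond_seed = stage_seeds[preset]
        with _stage(f"simulate:{preset}", manifest):
            if geometry.is_reference:
                sim = simulate_reference(phantom, geometry, noise, n_meas,
                                         seed=cond_seed)
                lr_list = sim.passes
            else:
                sim = simulate_acquisition(phantom, geometry, noise, n_meas,
                                           seed=cond_seed)
                lr_list = sim.lr_sets
            if cfg.get("write_volumes", True):
                for i, series in enumerate(lr_list):
                    p = write_volume_series(
                        series, out_dir / f"{preset}_set{i}.nii.gz")
                    manifest.record_output(f"simulate:{preset}", p)

        with _stage(f"reconstruct:{preset}", manifest):
            if geometry.is_reference:
                hr_perf = perfusion_frames(sim.merged())
                hr_m0 = sim.merged_m0().mean_volume()
            else:
                op = build_forward_operator(geometry)
                perf_sets = [perfusion_frames(s) for s in sim.lr_sets]
                result = reconstruct_series(perf_sets, op, ReconConfig(lam=lam))
                hr_perf = result.series
                m0_result = reconstruct_series(sim.m0_sets, op,
                                               ReconConfig(lam=lam))
                hr_m0 = m0_result.series.mean_volume()
                save_json(result.inverse.diagnostics(),
                          out_dir / f"{preset}_recon_diagnostics.json")
                manifest.record_output(
                    f"reconstruct:{preset}",
                    out_dir / f"{preset}_recon_diagnostics.json")
            if cfg.get("write_volumes", True):
                p = write_volume_series(hr_perf,
                                        out_dir / f"{preset}_perfusion_hr.nii.gz")
                manifest.record_output(f"reconstruct:{preset}", p)
                m0_series = VolumeSeries(hr_m0[..., None], ("m0",),
                                         hr_perf.spacing,
                                         slab_start=hr_perf.slab_start)
                p = write_volume_series(m0_series,
                                        out_dir / f"{preset}_m0_hr.nii.gz")
                manifest.record_output(f"reconstruct:{preset}", p)

        with _stage(f"metrics:{preset}", manifest):
            slab = slice(sim.slab_start,
                         sim.slab_start + hr_perf.n_slices)
            gm = gm_mask(phantom.gm_probability[:, :, slab], 0.9)
            report = snr_report(hr_perf, gm, condition=preset, lam=lam)
            reports.append(report.as_dict())

        if cfg.get("quantify", True):
            with _stage(f"quantify:{preset}", manifest):
                params = CBFParams(label_duration_ms=geometry.label_duration_ms,
                                   pld_ms=geometry.pld_ms)
                offsets = hr_slice_timing(geometry)
                result = quantify_cbf(hr_perf.mean_volume(), hr_m0, params,
                                      slice_offsets_ms=offsets)
                rois = roi_means(result.cbf,
                                 phantom.labels[:, :, slab],
                                 names={1: "csf", 2: "wm", 3: "gm"})
                p = save_json(
                    {"params": params.as_dict(),
                     "m0_threshold": result.m0_threshold,
                     "n_masked": result.n_masked,
                     "roi_means": rois.to_dict(orient="records")},
                    out_dir / f"{preset}_cbf.json")
                manifest.record_output(f"quantify:{preset}", p)

    save_json({"reports": reports}, out_dir / "snr_reports.json")
    manifest.record_output("metrics", out_dir / "snr_reports.json")
    manifest.save(out_dir / "manifest.json")
    return manifest
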