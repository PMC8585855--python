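"""NIfTI / JSON / YAML input-output and run manifests.

Volumes travel as NIfTI-1 with the slice direction on the third axis; the
affine encodes the voxel spacing with the slab origin at zero (slice 0 most
inferior).  Frame labels, which NIfTI cannot carry, live in a JSON sidecar
next to each image (``<stem>.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from .volumes import M0, VolumeSeries

__all__ = ["read_volume_series", "write_volume_series", "load_config",
           "RunManifest", "save_json", "load_json"]


class IOError_(ValueError):
    """Inconsistent or unreadable input files."""


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume_series(series: VolumeSeries, path: str | Path,
                        sidecar: bool = True) -> Path:
    """Write a series as NIfTI (4-D, or 3-D for one frame) plus sidecar."""
    path = Path(path)
    data = series.data
    if data.shape[3] == 1:
        data = data[..., 0]
    affine = np.diag(list(series.spacing) + [1.0])
    affine[2, 3] = series.slab_start * series.spacing[2]
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(series.spacing[: data.ndim][:3] + (
        () if data.ndim == 3 else (1.0,)))
    nib.save(img, str(path))
    if sidecar:
        meta = {
            "frame_labels": list(series.frame_labels),
            "spacing_mm": list(series.spacing),
            "slab_start": series.slab_start,
            "meta": _jsonable(series.meta),
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_volume_series(
    paths: str | Path | Sequence[str | Path],
    frame_labels: Sequence[str] | None = None,
    slice_axis: int = 2,
) -> VolumeSeries:
    """Read one or more NIfTI files into a :class:`VolumeSeries`.

    Multiple files are concatenated along the frame axis and must share
    shape and spacing (mismatches raise, naming the file).  Frame labels
    come from ``frame_labels``, else the JSON sidecar, else default to
    ``m0`` for single-frame input / ``perfusion`` otherwise.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if slice_axis != 2:
        raise IOError_("the slice direction must be the third array axis")
    blocks, spacing0, shape0, sidecar_labels = [], None, None, []
    slab_start = 0
    meta: dict = {}
    for p in paths:
        p = Path(p)
        img = nib.load(str(p))
        arr = np.asarray(img.get_fdata(), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., np.newaxis]
        if arr.ndim != 4:
            raise IOError_(f"{p}: expected 3-D or 4-D image, got {arr.ndim}-D")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if shape0 is None:
            shape0, spacing0 = arr.shape[:3], spacing
        else:
            if arr.shape[:3] != shape0:
                raise IOError_(f"{p}: shape {arr.shape[:3]} differs from "
                               f"first file {shape0}")
            if not np.allclose(spacing, spacing0):
                raise IOError_(f"{p}: spacing {spacing} differs from "
                               f"first file {spacing0}")
        side = _sidecar_path(p)
        if side.exists():
            info = json.loads(side.read_text())
            sidecar_labels.extend(info.get("frame_labels", []))
            slab_start = int(info.get("slab_start", slab_start))
            meta.update(info.get("meta", {}))
        blocks.append(arr)
    data = np.concatenate(blocks, axis=3)
    if frame_labels is not None:
        labels = tuple(frame_labels)
    elif len(sidecar_labels) == data.shape[3]:
        labels = tuple(sidecar_labels)
    else:
        labels = (M0,) if data.shape[3] == 1 else ("perfusion",) * data.shape[3]
    return VolumeSeries(data=data, frame_labels=labels, spacing=spacing0,
                        slab_start=slab_start, meta=meta)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def save_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2))
    return path


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, outputs, timings."""

    config: dict
    seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = ""

    def record_output(self, stage: str, path: str | Path) -> None:
        self.outputs.setdefault(stage, []).append(str(path))

    def save(self, path: str | Path) -> Path:
        return save_json({
            "config": self.config,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "outputs": self.outputs,
            "timings_s": self.timings_s,
            "warnings": self.warnings,
            "version": self.version,
        }, path)
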