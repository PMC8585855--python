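"""In-memory 4-D image series with frame labels.

The slice direction is the third array axis; frames are the fourth.
Frame labels follow ASL conventions: ``label``/``control`` pairs,
``perfusion`` difference frames, or ``m0`` proton-density frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["VolumeSeries", "perfusion_frames", "LABEL", "CONTROL",
           "PERFUSION", "M0"]

LABEL = "label"
CONTROL = "control"
PERFUSION = "perfusion"
M0 = "m0"

_KNOWN = {LABEL, CONTROL, PERFUSION, M0}


@dataclass
class VolumeSeries:
    """A 4-D stack ``(x, y, slice, frame)`` with per-frame labels.

    ``slab_start`` locates the series' first slice on the thin-slice grid of
    the phantom/study it came from (sub-slab acquisitions are centred).
    """

    data: np.ndarray
    frame_labels: tuple[str, ...]
    spacing: tuple[float, float, float]
    slab_start: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3-D or 4-D data, got {self.data.ndim}-D")
        self.frame_labels = tuple(self.frame_labels)
        if len(self.frame_labels) != self.data.shape[3]:
            raise ValueError(
                f"{len(self.frame_labels)} frame labels for "
                f"{self.data.shape[3]} frames")
        unknown = set(self.frame_labels) - _KNOWN
        if unknown:
            raise ValueError(f"unknown frame labels: {sorted(unknown)}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        self.spacing = tuple(float(s) for s in self.spacing)

    # -- basic accessors ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def frame(self, index: int) -> np.ndarray:
        return self.data[..., index]

    def select(self, label: str) -> "VolumeSeries":
        """Sub-series of all frames carrying ``label`` (order preserved)."""
        idx = [i for i, l in enumerate(self.frame_labels) if l == label]
        if not idx:
            raise ValueError(f"series has no {label!r} frames")
        return replace(self, data=self.data[..., idx],
                       frame_labels=tuple(self.frame_labels[i] for i in idx))

    def mean_volume(self, label: str | None = None) -> np.ndarray:
        series = self if label is None else self.select(label)
        return series.data.mean(axis=3)

    def with_frames(self, data: np.ndarray,
                    frame_labels: Sequence[str]) -> "VolumeSeries":
        return replace(self, data=data, frame_labels=tuple(frame_labels))


def perfusion_frames(series: VolumeSeries) -> VolumeSeries:
    """Pairwise control-minus-label difference series.

    Requires equal numbers of label and control frames, paired in
    acquisition order.  A series already made of perfusion frames is
    returned unchanged.
    """
    if all(l == PERFUSION for l in series.frame_labels):
        return series
    labels = series.select(LABEL)
    controls = series.select(CONTROL)
    if labels.n_frames != controls.n_frames:
        raise ValueError(
            f"unpaired frames: {labels.n_frames} label vs "
            f"{controls.n_frames} control")
    diff = controls.data - labels.data
    return series.with_frames(diff, (PERFUSION,) * labels.n_frames)
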