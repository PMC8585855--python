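"""Forward model: thin-slice profiles to stacked shifted thick-slice data.

The acquisition of ``n_set`` shifted thick-slice stacks is linear in the
thin-slice signal and decouples over in-plane position, so it is one small
matrix ``A`` applied to every slice-direction column:

    A @ I_hr = I_lr

Rows are ordered set-major: row ``k * n_thick + t`` is thick slice ``t`` of
shift set ``k``.  With the boxcar (ideal) slice profile, that row averages
the ``n_set`` thin slices it covers, so the thick-slice value is the *mean*
of its footprint and signal units are preserved across resolutions.  Rows
whose footprint extends past the slab edge keep only the in-slab weights,
without renormalisation (zero signal outside the slab); regularisation
stabilises the weakly determined edge slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .geometry import AcquisitionGeometry, GeometryError, hr_grid

__all__ = ["SliceProfile", "ForwardOperator", "build_forward_operator",
           "apply_forward"]


@dataclass(frozen=True)
class SliceProfile:
    """Slice-excitation profile sampled on the thin-slice grid.

    ``weights`` are the per-thin-slice sensitivities of one thick slice and
    sum to one (averaging convention).  Only the boxcar family is required;
    the abstraction leaves room for measured/SLR profiles.
    """

    kind: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("profile weights must be a non-empty 1-D array")
        if np.any(w < 0):
            raise ValueError("profile weights must be non-negative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("profile weights must sum to 1 (averaging convention)")

    @property
    def support_thin_slices(self) -> int:
        return int(self.weights.size)

    @classmethod
    def boxcar(cls, support: int) -> "SliceProfile":
        """Ideal rectangular profile covering ``support`` thin slices."""
        if support < 1:
            raise ValueError("boxcar support must be >= 1")
        return cls(kind="boxcar", weights=np.full(support, 1.0 / support))


@dataclass(frozen=True)
class ForwardOperator:
    """The banded averaging matrix of one SLIDER protocol.

    ``matrix`` is stored sparse (CSR); :meth:`dense` materialises it for the
    SVD.  ``row_map[r] = (set index, thick-slice index)`` for each row.
    """

    matrix: sparse.csr_array
    row_map: np.ndarray  # (n_rows, 2) int
    geometry: AcquisitionGeometry
    profile: SliceProfile

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_hr(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_set(self) -> int:
        return self.geometry.n_set

    @property
    def n_thick(self) -> int:
        return self.geometry.n_thick_slices

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def rows_for_set(self, set_index: int) -> np.ndarray:
        """Dense (n_thick, n_hr) sub-matrix of one shift set."""
        if not 0 <= set_index < self.n_set:
            raise IndexError(f"set index {set_index} out of range")
        start = set_index * self.n_thick
        return self.matrix[start:start + self.n_thick].toarray()

    def project(self, hr: np.ndarray, set_index: int | None = None) -> np.ndarray:
        """Apply the operator along the last axis of ``hr``.

        With ``set_index`` given, returns the thick-slice data of that set
        (last axis ``n_thick``); otherwise all stacked rows (``n_rows``).
        """
        hr = np.asarray(hr)
        if hr.shape[-1] != self.n_hr:
            raise ValueError(
                f"last axis must have {self.n_hr} thin slices, got {hr.shape[-1]}")
        A = self.dense() if set_index is None else self.rows_for_set(set_index)
        return hr @ A.T

    def export_matrix_market(self, path) -> None:
        """Write the operator in Matrix Market format (debugging aid)."""
        from scipy.io import mmwrite

        mmwrite(str(path), self.matrix)


def build_forward_operator(
    geometry: AcquisitionGeometry,
    profile: SliceProfile | None = None,
) -> ForwardOperator:
    """Construct the stacked-shift averaging operator for ``geometry``.

    Thick slice ``t`` of shift set ``k`` covers thin slices
    ``t * n_set + shift_sign * k + [0, support)``; out-of-slab weights are
    dropped without renormalisation.  For ``n_set == 1`` with the boxcar
    profile the operator is the identity.
    """
    if geometry.is_reference:
        raise GeometryError(
            "the interleaved two-pass reference has no deblurring operator; "
            "merge the passes instead")
    if profile is None:
        profile = SliceProfile.boxcar(geometry.n_set)
    if profile.kind == "boxcar" and profile.support_thin_slices != geometry.n_set:
        raise GeometryError(
            f"boxcar support {profile.support_thin_slices} incompatible with "
            f"n_set={geometry.n_set}")
    n_set = geometry.n_set
    n_thick = geometry.n_thick_slices
    n_hr = hr_grid(geometry).n_slices
    support = profile.support_thin_slices

    rows, cols, vals, row_map = [], [], [], []
    for k in range(n_set):
        for t in range(n_thick):
            r = k * n_thick + t
            start = t * n_set + geometry.shift_sign * k
            for i in range(support):
                j = start + i
                if 0 <= j < n_hr:
                    rows.append(r)
                    cols.append(j)
                    vals.append(profile.weights[i])
            row_map.append((k, t))
    matrix = sparse.csr_array(
        (vals, (rows, cols)), shape=(n_set * n_thick, n_hr))
    return ForwardOperator(
        matrix=matrix,
        row_map=np.asarray(row_map, dtype=int),
        geometry=geometry,
        profile=profile,
    )


def apply_forward(operator: ForwardOperator, hr_column: np.ndarray) -> np.ndarray:
    """Stacked thick-slice measurements of one thin-slice column.

    Output is ordered by ``operator.row_map`` (set-major).
    """
    hr_column = np.asarray(hr_column, dtype=float)
    if hr_column.shape != (operator.n_hr,):
        raise ValueError(
            f"expected column of length {operator.n_hr}, got {hr_column.shape}")
    return operator.matrix @ hr_column
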