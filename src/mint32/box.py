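"""Periodic-box geometry and the MINT32 per-axis scale factors.

A MINT32 coordinate maps one periodic box length onto the full signed
32-bit integer cycle.  The scale factor ``S_alpha = 2**32 / L_alpha``
(counts per Angstrom) is the *only* free parameter of the representation,
and it is not actually free: any other choice would break the property
that integer overflow coincides exactly with the periodic boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TWO32 = 2**32
TWO31 = 2**31

__all__ = [
    "TWO32",
    "TWO31",
    "BoxSpec",
    "ScaleFactors",
    "make_scale_factors",
    "rescale_box",
    "InvalidBoxError",
    "InvalidCellError",
]


class InvalidBoxError(ValueError):
    """Raised for non-positive or otherwise unusable box dimensions."""


class InvalidCellError(ValueError):
    """Raised for a singular or missing triclinic cell matrix."""


@dataclass(frozen=True)
class BoxSpec:
    """Orthorhombic or triclinic periodic cell.

    Parameters
    ----------
    lengths : array-like of 3 floats
        Box side lengths ``L_alpha`` in Angstrom.  In triclinic mode these
        are only used for reporting; the geometry lives in ``cell_matrix``.
    centered : bool
        If True (the default and the convention used throughout), Cartesian
        coordinates live in ``[-L/2, +L/2)`` per axis and fractional
        coordinates in ``[-1/2, +1/2)``.
    cell_matrix : (3, 3) array, optional
        Lattice vectors in *columns*, Angstrom.  Orthorhombic boxes are the
        special case ``H = diag(L)``.
    """

    lengths: np.ndarray
    centered: bool = True
    cell_matrix: np.ndarray | None = field(default=None)

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise InvalidBoxError(f"box lengths must be positive and finite, got {lengths}")
        object.__setattr__(self, "lengths", lengths)
        if self.cell_matrix is not None:
            H = np.asarray(self.cell_matrix, dtype=np.float64).reshape(3, 3)
            if not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12:
                raise InvalidCellError("cell matrix must be finite and invertible")
            object.__setattr__(self, "cell_matrix", H)

    @classmethod
    def cubic(cls, L: float, centered: bool = True) -> "BoxSpec":
        return cls(lengths=np.array([L, L, L], dtype=np.float64), centered=centered)

    @classmethod
    def orthorhombic(cls, Lx: float, Ly: float, Lz: float, centered: bool = True) -> "BoxSpec":
        return cls(lengths=np.array([Lx, Ly, Lz], dtype=np.float64), centered=centered)

    @classmethod
    def truncated_octahedron(cls, a: float) -> "BoxSpec":
        """Standard truncated-octahedron cell with box length parameter ``a``.

        All lattice angles equal ``arccos(-1/3) ~ 109.47 deg``; the cell
        matrix is upper triangular with unit-length columns times ``a`` and
        condition number exactly 2.
        """
        if a <= 0:
            raise InvalidBoxError("box length parameter a must be positive")
        H = a * np.array(
            [
                [1.0, -1.0 / 3.0, -1.0 / 3.0],
                [0.0, 2.0 * math.sqrt(2.0) / 3.0, -math.sqrt(2.0) / 3.0],
                [0.0, 0.0, math.sqrt(6.0) / 3.0],
            ]
        )
        # reported per-axis lengths are the perpendicular widths along H's rows
        lengths = 1.0 / np.linalg.norm(np.linalg.inv(H), axis=1)
        return cls(lengths=lengths, centered=True, cell_matrix=H)

    @property
    def is_triclinic(self) -> bool:
        return self.cell_matrix is not None

    @property
    def H(self) -> np.ndarray:
        if self.cell_matrix is None:
            return np.diag(self.lengths)
        return self.cell_matrix

    def require_cell(self) -> np.ndarray:
        if self.cell_matrix is None:
            raise InvalidCellError("operation requires a triclinic cell matrix")
        return self.cell_matrix


@dataclass(frozen=True)
class ScaleFactors:
    """Per-axis scale ``S_alpha = 2**32 / L_alpha`` in counts per Angstrom.

    ``S`` is stored as the exact real value in 64-bit working precision
    (not the rounded integer sometimes quoted for presentation); its
    inverse is the uniform grid spacing ``L_alpha / 2**32``.
    """

    S: np.ndarray
    lengths: np.ndarray

    @property
    def inverse(self) -> np.ndarray:
        """Grid spacing, Angstrom per count."""
        return self.lengths / TWO32

    def __iter__(self):
        return iter(self.S)


def make_scale_factors(box: BoxSpec) -> ScaleFactors:
    """Scale factors ``S_alpha = 2**32 / L_alpha`` for an orthorhombic box."""
    return ScaleFactors(S=TWO32 / box.lengths, lengths=box.lengths.copy())


def rescale_box(S_old: ScaleFactors, L_new) -> ScaleFactors:
    """New scale factors after an instantaneous box rescale.

    Integer coordinates are deliberately *not* touched by a rescale: the
    fractional position ``X / 2**32`` is exactly invariant, so decoded
    Cartesian positions scale by ``L_new / L_old`` with no accumulated
    rounding, and repeated rescales are exactly reversible.
    """
    L_new = np.asarray(L_new, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(L_new)) or np.any(L_new <= 0):
        raise InvalidBoxError(f"new box lengths must be positive, got {L_new}")
    return ScaleFactors(S=TWO32 / L_new, lengths=L_new)
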