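"""Closed-form precision models for FP32 versus MINT32 coordinates.

Two distinct FP32 error conventions are used deliberately:

* the *spacing* (full ulp) at the box edge, which quantifies the worst-case
  resolution of the stored coordinate grid, and
* the *rounding error* (half ulp) at the centered-box edge, which is the
  worst-case representation error of a coordinate and is the quantity that
  propagates into PME charge-assignment jitter.

The resolution table uses the first; the grid-alignment analysis uses the
second.  MINT32 has a single uniform spacing ``L / 2**32`` everywhere, so
its worst-case representation error is ``L / 2**33``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .box import TWO32, BoxSpec

FP32_UNIT_ROUNDOFF = 2.0**-24  # u: half the relative spacing of FP32

__all__ = [
    "FP32_UNIT_ROUNDOFF",
    "fp32_ulp",
    "fp32_rounding_error",
    "mint32_spacing",
    "ResolutionRow",
    "resolution_table",
    "GridAlignmentRow",
    "pme_alignment_row",
    "bspline_m4",
    "bspline_m4_max_derivative",
    "TruncOctModel",
    "trunc_oct_cell",
    "trunc_oct_error_bound",
    "worst_case_cutoff_du",
    "force_error_estimate",
]


def fp32_ulp(x: float) -> float:
    """Spacing of the 32-bit float grid at ``|x|`` (Angstrom).

    A step function, constant on binades: ``2**(e - 23)`` with
    ``e = floor(log2 |x|)`` for normal ``x``.  ``ulp(0)`` is reported as the
    smallest normal spacing.
    """
    if not math.isfinite(x):
        raise ValueError("x must be finite")
    if x == 0.0:
        return float(np.spacing(np.float32(np.finfo(np.float32).tiny)))
    return float(np.spacing(np.float32(abs(x))))


def fp32_rounding_error(x: float) -> float:
    """Worst-case FP32 representation error at ``|x|``: half the spacing."""
    return 0.5 * fp32_ulp(x)


def mint32_spacing(L: float) -> float:
    """Uniform MINT32 grid spacing ``L / 2**32`` (Angstrom)."""
    return L / TWO32


@dataclass(frozen=True)
class ResolutionRow:
    """One row of the FP32-vs-MINT32 spatial-resolution comparison."""

    L: float
    fp32_worst: float        # ulp at the box edge x = L (uncentered box)
    mint32_uniform: float    # L / 2**32, position independent
    ratio_uncentered: float
    ratio_centered: float    # uses the ulp at x = L/2


def resolution_table(L_list) -> list[ResolutionRow]:
    """Worst-case FP32 spacing against the uniform MINT32 spacing.

    The FP32 worst case is evaluated at the box edge: ``x = L`` for an
    uncentered ``[0, L]`` box, ``x = L/2`` for a centered box.
    """
    rows = []
    for L in L_list:
        if L <= 0:
            raise ValueError("box lengths must be positive")
        mint = mint32_spacing(L)
        edge = fp32_ulp(L)
        rows.append(
            ResolutionRow(
                L=float(L),
                fp32_worst=edge,
                mint32_uniform=mint,
                ratio_uncentered=edge / mint,
                ratio_centered=fp32_ulp(L / 2.0) / mint,
            )
        )
    return rows


@dataclass(frozen=True)
class GridAlignmentRow:
    """PME charge-assignment alignment error for one (L, K) system."""

    L: float
    K: int
    representation: str
    dx: float      # coordinate representation error, Angstrom
    dg: float      # fractional grid-position error dx * K / L
    dW: float      # B-spline weight error bound (2/3) * dg


def pme_alignment_row(L: float, K: int, representation: str) -> GridAlignmentRow:
    """Worst-case particle-to-mesh alignment error for a PME grid.

    A particle at ``x`` maps to the fractional grid coordinate
    ``g = x K / L``; a coordinate error ``dx`` becomes a grid-position
    error ``dg = dx K / L`` and a fourth-order B-spline weight error
    ``dW <= (2/3) dg`` (2/3 is the maximum derivative of M4).

    FP32 uses the worst-case rounding error at the centered-box edge,
    ``ulp(L/2) / 2``; MINT32 uses the uniform ``L / 2**33``, making
    ``dg = K / 2**33`` independent of the box size.
    """
    if K < 1 or L <= 0:
        raise ValueError("require K >= 1 and L > 0")
    if representation == "fp32":
        dx = fp32_rounding_error(L / 2.0)
    elif representation == "mint32":
        dx = L / 2.0**33
    else:
        raise ValueError(f"unknown representation {representation!r}")
    dg = dx * K / L
    return GridAlignmentRow(L=float(L), K=int(K), representation=representation,
                            dx=dx, dg=dg, dW=(2.0 / 3.0) * dg)


def bspline_m4(u: float) -> np.ndarray:
    """Fourth-order cardinal B-spline charge-assignment weights.

    ``u`` is the fractional offset within a grid cell, in ``[0, 1)``.  The
    four weights are the values of the cardinal B-spline M4 at the four
    covered grid points; they are non-negative and sum to one (partition
    of unity).
    """
    u = float(u)
    if not 0.0 <= u < 1.0:
        raise ValueError("fractional offset must lie in [0, 1)")
    v = 1.0 - u
    return np.array(
        [
            v * v * v / 6.0,
            (3.0 * u**3 - 6.0 * u**2 + 4.0) / 6.0,
            (-3.0 * u**3 + 3.0 * u**2 + 3.0 * u + 1.0) / 6.0,
            u * u * u / 6.0,
        ]
    )


def _bspline_m4_derivative(u: float) -> np.ndarray:
    u = float(u)
    return np.array(
        [
            -0.5 * (1.0 - u) ** 2,
            (9.0 * u**2 - 12.0 * u) / 6.0,
            (-9.0 * u**2 + 6.0 * u + 3.0) / 6.0,
            0.5 * u**2,
        ]
    )


def bspline_m4_max_derivative(n_grid: int = 4001, refine: int = 60) -> float:
    """Maximum of ``|d w_k / d u|`` over the unit cell, by grid + bisection.

    The analytic extremum is 2/3; this searches a dense grid and refines by
    golden-section around the best point so the value is located rather
    than asserted.
    """
    us = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    vals = np.array([np.max(np.abs(_bspline_m4_derivative(u))) for u in us])
    i = int(np.argmax(vals))
    lo = us[max(i - 1, 0)]
    hi = us[min(i + 1, n_grid - 1)]
    f = lambda u: -np.max(np.abs(_bspline_m4_derivative(u)))
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    for _ in range(refine):
        if f(c) < f(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    best = 0.5 * (a + b)
    return float(np.max(np.abs(_bspline_m4_derivative(best))))


@dataclass(frozen=True)
class TruncOctModel:
    """Error model for the truncated-octahedron fractional representation."""

    a: float
    H: np.ndarray
    unit_roundoff: float
    gamma2: float
    cutoff: float

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.H))

    @property
    def perpendicular_widths(self) -> np.ndarray:
        """Distance between opposite cell faces along each lattice direction."""
        return 1.0 / np.linalg.norm(np.linalg.inv(self.H), axis=1)


def trunc_oct_cell(a: float, cutoff: float = 8.0) -> TruncOctModel:
    """Truncated-octahedron cell and the constants of its error bound.

    ``gamma2`` is the two-term IEEE-754 error-accumulation constant,
    taken as ``2u`` with ``u = 2**-24`` the FP32 unit roundoff.
    """
    box = BoxSpec.truncated_octahedron(a)
    u = FP32_UNIT_ROUNDOFF
    return TruncOctModel(a=float(a), H=box.H, unit_roundoff=u, gamma2=2.0 * u,
                         cutoff=float(cutoff))


def _int32_to_fp32_error(dU: np.ndarray) -> np.ndarray:
    """Worst-case error (counts) narrowing an integer of magnitude |dU| to FP32.

    Half the spacing of the FP32 grid at that magnitude — the staircase
    quantum of the direct conversion path.
    """
    dU = np.abs(np.asarray(dU, dtype=np.float64))
    out = np.zeros_like(dU)
    nz = dU > 0
    out[nz] = 0.5 * np.spacing(dU[nz].astype(np.float32)).astype(np.float64)
    return out


def trunc_oct_error_bound(model: TruncOctModel, du) -> np.ndarray:
    """Per-component bound on the reconstructed Cartesian displacement error.

    For fractional displacements ``du`` (|du_j| <= 1/2), the error of
    ``dr = H float(dU) / 2**32`` is bounded by

        |err_i| <= gamma2 sum_j |H_ij||du_j|
                   + sum_j |H_ij| (eta_j / 2**32 + |du_j| u)

    where ``eta_j`` is the worst-case INT32->FP32 conversion error at the
    integer magnitude ``|du_j| * 2**32``.
    """
    du = np.abs(np.asarray(du, dtype=np.float64).reshape(3))
    if np.any(du > 0.5):
        raise ValueError("fractional displacements must satisfy |du| <= 1/2")
    eta = _int32_to_fp32_error(du * TWO32)
    absH = np.abs(model.H)
    return model.gamma2 * absH @ du + absH @ (eta / TWO32 + du * model.unit_roundoff)


def worst_case_cutoff_du(model: TruncOctModel) -> np.ndarray:
    """Conservative per-component |du| for a separation at the cutoff.

    Takes every component simultaneously at ``cutoff / w_j`` where ``w_j``
    is the perpendicular width of the cell along lattice direction ``j``.
    """
    return model.cutoff / model.perpendicular_widths


def force_error_estimate(r: float, dr: float, potential: str = "lj",
                         epsilon: float = 1.0, sigma: float = 1.0,
                         kqq: float = 1.0) -> float:
    """First-order force error ``|V''(r)| dr`` from a coordinate error ``dr``.

    The Lennard-Jones estimate keeps only the dominant repulsive stiffness
    (``V'' ~ r**-14``); the Coulomb one uses ``V'' = 2 k q1 q2 / r**3``.
    Used for comparing the noise floors of the two coordinate
    representations, where only the ratio matters.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if dr < 0:
        raise ValueError("dr must be non-negative")
    if potential == "lj":
        stiffness = 156.0 * 4.0 * epsilon * sigma**12 / r**14
    elif potential == "coulomb":
        stiffness = 2.0 * abs(kqq) / r**3
    else:
        raise ValueError(f"unknown potential {potential!r}")
    return stiffness * dr
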