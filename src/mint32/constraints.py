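"""SHAKE distance constraints and RATTLE velocity constraints on any
coordinate backend, including the MINT32 integer grid.

All constraint geometry (reference vectors, current distances, Lagrange
corrections) is computed in 64-bit floating point; only the coordinate
*differences* come from the backend representation, and corrections are
rounded back into it (for MINT32, ``dX_corr = rint(dx_corr * S)`` applied
by exact modular addition).  The achievable tolerance is therefore bounded
below by the representation grid: a tolerance finer than roughly twice the
grid spacing cannot converge and triggers a configuration warning.

The iteration is a Gauss-Seidel sweep in ascending constraint order.
Constraints that share no atom commute, so the sweep is organised into
"colors" (greedily built independent groups) that are processed
sequentially while each group is updated as a vectorised block — identical
arithmetic to the sequential sweep, without a Python-level loop per
constraint.  A sweep whose largest implied correction is below half the
tolerance terminates the iteration; the final residuals are then verified
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .backends import CoordinateBackend, Fp32EmulatedBackend, Fp64Backend, Mint32Backend
from .fixedpoint import ConversionPolicy

__all__ = ["ConstraintSet", "ConstraintWarning", "ConstraintError",
           "shake", "rattle_velocities"]


class ConstraintWarning(UserWarning):
    pass


class ConstraintError(RuntimeError):
    """Non-convergence; carries the worst residual for diagnosis."""


def _color_groups(pairs: np.ndarray) -> list[np.ndarray]:
    """Greedy partition of constraints into atom-disjoint groups.

    Within a group no two constraints share an atom, so a vectorised
    Gauss-Seidel update over the group equals processing its members
    sequentially in ascending order.
    """
    groups: list[list[int]] = []
    group_atoms: list[set[int]] = []
    for c, (i, j) in enumerate(pairs):
        for g, atoms in enumerate(group_atoms):
            if i not in atoms and j not in atoms:
                groups[g].append(c)
                atoms.update((int(i), int(j)))
                break
        else:
            groups.append([c])
            group_atoms.append({int(i), int(j)})
    return [np.asarray(g, dtype=np.int64) for g in groups]


class _Group:
    """Cached index arrays for one atom-disjoint constraint group."""

    __slots__ = ("idx", "i", "j", "both", "d0sq", "d0x2", "inv_mi", "inv_mj",
                 "red", "masses_key")

    def __init__(self, idx, pairs, d0):
        self.idx = idx
        self.i = pairs[idx, 0]
        self.j = pairs[idx, 1]
        self.both = np.concatenate([self.i, self.j])
        self.d0sq = d0[idx] ** 2
        self.d0x2 = 2.0 * d0[idx]
        self.masses_key = None

    def bind_masses(self, masses):
        key = id(masses)
        if self.masses_key != key:
            inv = 1.0 / np.asarray(masses, dtype=np.float64)
            self.inv_mi = inv[self.i][:, None]
            self.inv_mj = inv[self.j][:, None]
            self.red = (inv[self.i] + inv[self.j])[:, None]
            self.masses_key = key


@dataclass
class ConstraintSet:
    """Holonomic distance constraints ``|x_i - x_j| = d0``.

    ``tolerance`` is the convergence criterion ``| r - d0 | <= tol`` in
    Angstrom (not the relative-squared convention some engines use).
    """

    pairs: np.ndarray                 # (nc, 2) atom indices
    d0: np.ndarray                    # (nc,) target lengths, Angstrom
    tolerance: float = 1e-7
    max_iterations: int = 500
    _groups: list = field(default=None, repr=False)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.d0 = np.asarray(self.d0, dtype=np.float64).reshape(-1)
        if np.any(self.d0 <= 0):
            raise ValueError("constraint target lengths must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if len(self.d0) != len(self.pairs):
            raise ValueError("pairs and d0 must have equal length")
        self._groups = [_Group(idx, self.pairs, self.d0)
                        for idx in _color_groups(self.pairs)]

    def __len__(self):
        return len(self.pairs)

    def check_resolution(self, backend: CoordinateBackend) -> None:
        """Warn when the tolerance is below what the coordinate grid resolves."""
        grid = float(np.max(backend.constraint_resolution))
        if self.tolerance < 2.0 * grid:
            warnings.warn(
                f"constraint tolerance {self.tolerance:g} A is below twice the "
                f"coordinate grid spacing {grid:g} A and may not be achievable",
                ConstraintWarning, stacklevel=2)


def _residuals(pos, constraints: ConstraintSet, backend: CoordinateBackend) -> np.ndarray:
    d = backend.pair_delta(pos, constraints.pairs[:, 0], constraints.pairs[:, 1],
                           bonded=True)
    return np.abs(np.sqrt(np.einsum("ij,ij->i", d, d)) - constraints.d0)


def _shake_compiled(pos, prev_pos, constraints: ConstraintSet,
                    backend: CoordinateBackend, masses: np.ndarray):
    """Run the sequential compiled sweep when it applies; None otherwise."""
    if not _kernels.HAVE_NUMBA:
        return None
    ii = np.ascontiguousarray(constraints.pairs[:, 0])
    jj = np.ascontiguousarray(constraints.pairs[:, 1])
    inv_m = 1.0 / np.asarray(masses, dtype=np.float64)
    if (isinstance(backend, Mint32Backend)
            and backend.bonded_policy is ConversionPolicy.PROMOTE_FP64):
        return int(_kernels._shake_int32(
            pos, prev_pos, ii, jj, constraints.d0, inv_m,
            backend.scale.S, 1.0 / backend.scale.S,
            constraints.tolerance, constraints.max_iterations))
    if isinstance(backend, (Fp64Backend, Fp32EmulatedBackend)):
        # both run their constraint geometry on the FP64 authoritative store
        return int(_kernels._shake_f64(
            pos, prev_pos, ii, jj, constraints.d0, inv_m,
            backend.lengths, constraints.tolerance, constraints.max_iterations))
    return None


def shake(pos, prev_pos, constraints: ConstraintSet, backend: CoordinateBackend,
          masses: np.ndarray) -> int:
    """Iteratively project positions onto the constraint manifold, in place.

    Reference bond vectors are taken from the previous time step's
    positions (the classic SHAKE linearisation); the correction for
    constraint ``(i, j)`` is applied equal-and-opposite weighted by inverse
    masses, so constraint forces are internal and conserve momentum.

    Returns the number of sweeps used.
    """
    tol = constraints.tolerance
    sweeps = _shake_compiled(pos, prev_pos, constraints, backend, masses)
    if sweeps is not None:
        if sweeps < 0:
            worst = float(np.max(_residuals(pos, constraints, backend)))
            raise ConstraintError(
                f"SHAKE did not converge in {constraints.max_iterations} sweeps; "
                f"worst residual {worst:.3e} A (tolerance {tol:g} A)")
        return sweeps
    groups = constraints._groups
    refs = []
    for g in groups:
        g.bind_masses(masses)
        refs.append(backend.pair_delta(prev_pos, g.i, g.j, bonded=True))

    for sweep in range(1, constraints.max_iterations + 1):
        worst = 0.0
        for g, ref in zip(groups, refs):
            d = backend.pair_delta(pos, g.i, g.j, bonded=True)
            diff = np.einsum("ij,ij->i", d, d) - g.d0sq
            # |r - d0| ~ |r^2 - d0^2| / (2 d0) near convergence
            err = np.max(np.abs(diff) / g.d0x2)
            if err > worst:
                worst = err
            lam = (diff / (2.0 * np.einsum("ij,ij->i", d, ref)))[:, None] / g.red
            corr = lam * ref
            backend.apply_correction(
                pos, g.both,
                np.concatenate([-corr * g.inv_mi, corr * g.inv_mj]))
        if worst <= 0.5 * tol:
            if np.max(_residuals(pos, constraints, backend)) <= tol:
                return sweep
    worst = float(np.max(_residuals(pos, constraints, backend)))
    raise ConstraintError(
        f"SHAKE did not converge in {constraints.max_iterations} sweeps; "
        f"worst residual {worst:.3e} A (tolerance {tol:g} A)")


def rattle_velocities(vel: np.ndarray, pos, constraints: ConstraintSet,
                      backend: CoordinateBackend, masses: np.ndarray,
                      tolerance: float) -> int:
    """Project out velocity components along constraint directions, in place.

    Iterates until ``|(v_i - v_j) . rhat_ij| <= tolerance`` (Angstrom/fs)
    for every constraint.  Corrections are mass-weighted and internal.
    """
    if _kernels.HAVE_NUMBA:
        ii = np.ascontiguousarray(constraints.pairs[:, 0])
        jj = np.ascontiguousarray(constraints.pairs[:, 1])
        delta = backend.pair_delta(pos, ii, jj, bonded=True)
        inv_m = 1.0 / np.asarray(masses, dtype=np.float64)
        sweeps = int(_kernels._rattle(vel, np.ascontiguousarray(delta), ii, jj,
                                      inv_m, tolerance, constraints.max_iterations))
        if sweeps < 0:
            raise ConstraintError(
                f"RATTLE did not converge in {constraints.max_iterations} sweeps")
        return sweeps
    groups = constraints._groups
    dirs, inv_dsq, inv_dnorm = [], [], []
    for g in groups:
        g.bind_masses(masses)
        d = backend.pair_delta(pos, g.i, g.j, bonded=True)
        dsq = np.einsum("ij,ij->i", d, d)
        dirs.append(d)
        inv_dsq.append((1.0 / dsq)[:, None])
        inv_dnorm.append(1.0 / np.sqrt(dsq))

    for sweep in range(1, constraints.max_iterations + 1):
        worst = 0.0
        for g, d, idsq, idn in zip(groups, dirs, inv_dsq, inv_dnorm):
            vrel = vel[g.i] - vel[g.j]
            proj = np.einsum("ij,ij->i", vrel, d)
            err = np.max(np.abs(proj) * idn)
            if err > worst:
                worst = err
            lam = (proj[:, None] * idsq) / g.red
            vel[g.i] -= lam * d * g.inv_mi
            vel[g.j] += lam * d * g.inv_mj
        if worst <= tolerance:
            return sweep
    raise ConstraintError(
        f"RATTLE did not converge in {constraints.max_iterations} sweeps")
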