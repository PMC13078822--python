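"""Velocity-Verlet NVE engine over pluggable coordinate backends.

The engine is deliberately small and representation-agnostic: every pair
displacement goes through the backend's minimum-image operation, and the
position drift is applied by the backend (for MINT32 that is the integer
update ``X(t+dt) = X(t) + round(v dt S)`` whose modular wrap *is* the
periodic boundary).  Velocities, forces and energies are always 64-bit;
the quantity under study is the coordinate representation.

Energy drift is reported in units of ``k_B T / ns`` per degree of freedom
at 300 K, the normalisation that makes systems of different size
comparable: ``drift = slope(E_total vs t) / (dof * k_B * 300 K)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .backends import CoordinateBackend
from .box import BoxSpec
from .constraints import ConstraintSet, rattle_velocities, shake
from .forcefield import (
    ACC_CONV,
    CLASH_FLOOR,
    COULOMB,
    FIXED_FORCE_SCALE,
    KBOLTZ,
    KE_CONV,
    ClashError,
    ForceField,
)

__all__ = [
    "SystemState",
    "DriftReport",
    "compute_forces",
    "velocity_verlet_step",
    "run_nve",
    "drift_stability",
    "kinetic_energy",
    "kinetic_temperature",
]

DRIFT_REFERENCE_T = 300.0  # K


@dataclass
class SystemState:
    """Mutable simulation state.  Positions are Cartesian Angstrom; the
    engine converts them into the backend representation once at run start
    (after which self-wrapping or explicit wrapping keeps them in the box).
    """

    x: np.ndarray          # (N, 3) Cartesian positions, Angstrom
    v: np.ndarray          # (N, 3) velocities, Angstrom/fs
    masses: np.ndarray     # (N,) amu
    charges: np.ndarray    # (N,) e
    box: BoxSpec
    constraints: ConstraintSet | None = None

    def __post_init__(self):
        self.x = np.array(self.x, dtype=np.float64).reshape(-1, 3)
        self.v = np.array(self.v, dtype=np.float64).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=np.float64).reshape(-1)
        self.charges = np.asarray(self.charges, dtype=np.float64).reshape(-1)
        n = len(self.x)
        if not (len(self.v) == len(self.masses) == len(self.charges) == n):
            raise ValueError("inconsistent atom counts across state arrays")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocities must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.x)

    def dof(self) -> int:
        """3N minus constraints minus the removed center-of-mass momentum."""
        nc = len(self.constraints) if self.constraints is not None else 0
        return 3 * self.n_atoms - nc - 3

    def copy(self) -> "SystemState":
        return SystemState(x=self.x.copy(), v=self.v.copy(), masses=self.masses,
                           charges=self.charges, box=self.box,
                           constraints=self.constraints)


def kinetic_energy(state: SystemState) -> float:
    """Kinetic energy, kcal/mol."""
    return 0.5 * KE_CONV * float(np.sum(state.masses[:, None] * state.v**2))


def kinetic_temperature(state: SystemState) -> float:
    """Instantaneous kinetic temperature, K."""
    return 2.0 * kinetic_energy(state) / (state.dof() * KBOLTZ)


def remove_com_momentum(state: SystemState) -> None:
    p = state.masses[:, None] * state.v
    state.v -= p.sum(axis=0) / state.masses.sum()


class _PairList:
    """Verlet neighbour list over the O(N^2) pair set.

    Candidate pairs within ``cutoff + skin`` are re-selected whenever the
    accumulated upper bound on any atom's displacement exceeds ``skin/2``,
    which guarantees no interacting pair is ever missed.
    """

    def __init__(self, n: int, exclusions: np.ndarray, cutoff: float, skin: float = 1.0):
        ii, jj = np.triu_indices(n, k=1)
        if len(exclusions):
            ex = set(map(tuple, np.sort(exclusions, axis=1)))
            keep = np.fromiter(((i, j) not in ex for i, j in zip(ii, jj)),
                               dtype=bool, count=len(ii))
            ii, jj = ii[keep], jj[keep]
        self.all_ii = ii.astype(np.int64)
        self.all_jj = jj.astype(np.int64)
        self.cutoff = cutoff
        self.skin = skin
        self.ii = self.all_ii
        self.jj = self.all_jj
        self._travel = np.inf  # force a build on first use

    def update(self, pos, backend: CoordinateBackend, max_step: float) -> None:
        self._travel += max_step
        if self._travel < 0.5 * self.skin:
            return
        d = backend.pair_delta(pos, self.all_ii, self.all_jj)
        r2 = np.einsum("ij,ij->i", d, d)
        within = r2 < (self.cutoff + self.skin) ** 2
        self.ii = self.all_ii[within]
        self.jj = self.all_jj[within]
        self._travel = 0.0


def _accumulate(n: int, ii, jj, fpair: np.ndarray, mode: str) -> np.ndarray:
    """Sum per-pair force vectors into per-atom forces.

    ``fixed64`` rounds each contribution to the fixed-point grid
    (2**24 counts per kcal/mol/Angstrom) before summation; integer sums are
    exact, so the result is independent of pair order.
    """
    if mode == "fixed64":
        fpair = np.rint(fpair * FIXED_FORCE_SCALE)
    f = np.zeros((n, 3))
    for k in range(3):
        f[:, k] = (np.bincount(ii, weights=fpair[:, k], minlength=n)
                   - np.bincount(jj, weights=fpair[:, k], minlength=n))
    if mode == "fixed64":
        f /= FIXED_FORCE_SCALE
    return f


def _nonbonded(pos, state: SystemState, ff: ForceField, backend: CoordinateBackend,
               pairs: _PairList) -> tuple[np.ndarray, float]:
    ii, jj = pairs.ii, pairs.jj
    d = backend.pair_delta(pos, ii, jj)
    r2 = np.einsum("ij,ij->i", d, d)
    within = r2 < ff.cutoff**2
    ii, jj, d, r2 = ii[within], jj[within], d[within], r2[within]
    if r2.size and np.min(r2) < CLASH_FLOOR**2:
        k = int(np.argmin(r2))
        raise ClashError(ii[k], jj[k], float(np.sqrt(r2[k])))
    r = np.sqrt(r2)

    # Lennard-Jones with potential switching over [rc - w, rc]
    eps = np.sqrt(ff.epsilon[ii] * ff.epsilon[jj])
    sig = 0.5 * (ff.sigma[ii] + ff.sigma[jj])
    sr6 = (sig**2 / r2) ** 3
    vlj = 4.0 * eps * sr6 * (sr6 - 1.0)
    dvlj = 4.0 * eps * sr6 * (6.0 - 12.0 * sr6) / r  # dV/dr

    rc, ron = ff.cutoff, ff.cutoff - ff.switch_width
    rc2, ron2 = rc * rc, ron * ron
    denom = (rc2 - ron2) ** 3
    sw = np.ones_like(r)
    dsw = np.zeros_like(r)
    tail = r2 > ron2
    t = r2[tail]
    sw[tail] = (rc2 - t) ** 2 * (rc2 + 2.0 * t - 3.0 * ron2) / denom
    dsw[tail] = 12.0 * r[tail] * (rc2 - t) * (ron2 - t) / denom

    energy = float(np.sum(vlj * sw))
    dvdr = dvlj * sw + vlj * dsw

    # shifted-force Coulomb: V and dV/dr both vanish at the cutoff
    qq = COULOMB * state.charges[ii] * state.charges[jj]
    energy += float(np.sum(qq * (1.0 / r - 1.0 / rc + (r - rc) / rc2)))
    dvdr = dvdr + qq * (1.0 / rc2 - 1.0 / r2)

    fpair = (-dvdr / r)[:, None] * d  # force on atom ii
    return _accumulate(state.n_atoms, ii, jj, fpair, ff.accumulator), energy


def _bonded(pos, state: SystemState, ff: ForceField,
            backend: CoordinateBackend) -> tuple[np.ndarray, float]:
    n = state.n_atoms
    f = np.zeros((n, 3))
    energy = 0.0
    dtype = np.float32 if ff.bonded_precision == "fp32" else np.float64

    if len(ff.bonds):
        bi, bj = ff.bonds[:, 0], ff.bonds[:, 1]
        d = backend.pair_delta(pos, bi, bj, bonded=True).astype(dtype)
        r = np.sqrt(np.einsum("ij,ij->i", d, d), dtype=dtype)
        dev = r - ff.bond_r0.astype(dtype)
        energy += float(np.sum(ff.bond_k.astype(dtype) * dev * dev))
        coef = (-2.0 * ff.bond_k.astype(dtype) * dev / r).astype(dtype)
        fpair = (coef[:, None] * d).astype(np.float64)
        f += _accumulate(n, bi, bj, fpair, "fp64" if ff.accumulator == "fp64" else "fixed64")

    if len(ff.angles):
        a1, a2, a3 = ff.angles.T
        d21 = backend.pair_delta(pos, a1, a2, bonded=True).astype(dtype)
        d23 = backend.pair_delta(pos, a3, a2, bonded=True).astype(dtype)
        r21 = np.sqrt(np.einsum("ij,ij->i", d21, d21), dtype=dtype)
        r23 = np.sqrt(np.einsum("ij,ij->i", d23, d23), dtype=dtype)
        cosq = np.einsum("ij,ij->i", d21, d23) / (r21 * r23)
        cosq = np.clip(cosq, -1.0 + 1e-12, 1.0 - 1e-12)
        theta = np.arccos(cosq)
        dev = theta - ff.angle_theta0.astype(dtype)
        energy += float(np.sum(ff.angle_k.astype(dtype) * dev * dev))
        dV = 2.0 * ff.angle_k.astype(dtype) * dev
        sinq = np.sqrt(1.0 - cosq * cosq)
        c = (dV / sinq).astype(dtype)
        f1 = (c / r21)[:, None] * (d23 / r23[:, None] - cosq[:, None] * d21 / r21[:, None])
        f3 = (c / r23)[:, None] * (d21 / r21[:, None] - cosq[:, None] * d23 / r23[:, None])
        np.add.at(f, a1, f1.astype(np.float64))
        np.add.at(f, a3, f3.astype(np.float64))
        np.add.at(f, a2, -(f1 + f3).astype(np.float64))

    return f, energy


def compute_forces(state: SystemState, ff: ForceField, backend: CoordinateBackend,
                   pos=None, pairs: _PairList | None = None):
    """Forces (kcal/mol/Angstrom) and potential energy (kcal/mol).

    When called standalone, positions are encoded into the backend
    representation first; inside :func:`run_nve` the native positions and a
    persistent neighbour list are passed in.
    """
    ff.validate_box(state.box.lengths)
    if pos is None:
        pos = backend.from_cartesian(state.x)
    if pairs is None:
        pairs = _PairList(state.n_atoms, ff.exclusions, ff.cutoff)
        pairs.update(pos, backend, np.inf)
    f_nb, e_nb = _nonbonded(pos, state, ff, backend, pairs)
    f_b, e_b = _bonded(pos, state, ff, backend)
    return f_nb + f_b, e_nb + e_b


@dataclass
class DriftReport:
    """Energy time series and the fitted drift of an NVE run."""

    backend: str
    n_atoms: int
    dof: int
    dt_fs: float
    times_ps: np.ndarray
    e_total: np.ndarray
    e_kinetic: np.ndarray
    e_potential: np.ndarray
    slope_kcal_per_ns: float | None
    drift_kbt_per_ns_per_dof: float | None
    shake_max_residual: float = 0.0
    shake_mean_iterations: float = 0.0
    seed: int | None = None

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("times_ps", "e_total", "e_kinetic", "e_potential"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d, indent=2)


def _fit_drift(times_ps: np.ndarray, e_total: np.ndarray, dof: int,
               discard_fraction: float = 0.1):
    """OLS slope of total energy vs time, normalised to kBT/ns/DOF at 300 K.

    The first ``discard_fraction`` of the series is dropped as an
    equilibration transient before fitting.
    """
    if len(times_ps) < 3:
        return None, None
    start = int(np.floor(discard_fraction * len(times_ps)))
    t_ns = times_ps[start:] / 1000.0
    slope = np.polyfit(t_ns, e_total[start:], 1)[0]
    return float(slope), float(slope / (dof * KBOLTZ * DRIFT_REFERENCE_T))


def velocity_verlet_step(state: SystemState, ff: ForceField,
                         backend: CoordinateBackend, dt_fs: float):
    """One velocity-Verlet step on a standalone state (test/demo path).

    :func:`run_nve` carries its own loop for efficiency; this wrapper keeps
    the state Cartesian between calls.
    """
    pos = backend.from_cartesian(state.x)
    forces, _ = compute_forces(state, ff, backend, pos=pos)
    pos, forces, _, _ = _step(state, ff, backend, pos, forces, None, dt_fs)
    state.x = backend.to_cartesian(pos)
    return state


def _step(state, ff, backend, pos, forces, pairs, dt_fs, shake_stats=None):
    """Advance (pos, v, forces) by one velocity-Verlet step with constraints."""
    inv_m = 1.0 / state.masses[:, None]
    half = 0.5 * dt_fs * ACC_CONV
    state.v += half * forces * inv_m
    prev = pos if state.constraints is None else np.array(pos)
    pos = backend.advance(pos, state.v * dt_fs)
    if state.constraints is not None:
        before = backend.to_cartesian(pos)
        iters = shake(pos, prev, state.constraints, backend, state.masses)
        # fold the constraint displacement back into the half-step velocities;
        # the difference must be taken minimum-image: a correction that nudges
        # an atom across the periodic boundary is tiny, not ~L
        L = state.box.lengths
        corr = backend.to_cartesian(pos) - before
        corr -= L * np.rint(corr / L)
        state.v += corr / dt_fs
        if shake_stats is not None:
            shake_stats.append(iters)
    if pairs is not None:
        # after the fold, v * dt is the exact per-atom step displacement,
        # so the neighbour-list travel accounting is sound
        max_step = float(np.sqrt(np.max(np.sum(state.v**2, axis=1)))) * dt_fs
        pairs.update(pos, backend, max_step)
    forces, epot = compute_forces(state, ff, backend, pos=pos, pairs=pairs)
    state.v += half * forces * inv_m
    if state.constraints is not None:
        rattle_velocities(state.v, pos, state.constraints, backend, state.masses,
                          tolerance=state.constraints.tolerance / dt_fs)
    return pos, forces, epot, pairs


def run_nve(state: SystemState, ff: ForceField, backend: CoordinateBackend,
            n_steps: int, dt_fs: float = 1.0, report_interval: int = 20,
            seed: int | None = None, discard_fraction: float = 0.1) -> DriftReport:
    """Run NVE dynamics and fit the total-energy drift.

    Center-of-mass momentum is removed once at the start (accounted for in
    the degree-of-freedom count); energies are recorded every
    ``report_interval`` steps and the drift slope is fitted by ordinary
    least squares after discarding the initial transient.
    """
    state = state.copy()
    ff.validate_box(state.box.lengths)
    if state.constraints is not None:
        state.constraints.check_resolution(backend)
    remove_com_momentum(state)

    pos = backend.from_cartesian(state.x)
    pairs = _PairList(state.n_atoms, ff.exclusions, ff.cutoff)
    pairs.update(pos, backend, np.inf)
    forces, epot = compute_forces(state, ff, backend, pos=pos, pairs=pairs)

    shake_stats: list[int] = []
    times, etot, ekin, epots = [], [], [], []

    def record(step, epot_now):
        ke = kinetic_energy(state)
        times.append(step * dt_fs / 1000.0)  # ps
        ekin.append(ke)
        epots.append(epot_now)
        etot.append(ke + epot_now)

    record(0, epot)
    for step in range(1, n_steps + 1):
        pos, forces, epot, pairs = _step(state, ff, backend, pos, forces, pairs,
                                         dt_fs, shake_stats)
        if not np.isfinite(epot):
            raise RuntimeError(f"energy became non-finite at step {step}")
        if step % report_interval == 0:
            record(step, epot)

    state.x = backend.to_cartesian(pos)
    times = np.asarray(times)
    etot = np.asarray(etot)
    slope, drift = _fit_drift(times, etot, state.dof(), discard_fraction)

    max_res = 0.0
    if state.constraints is not None and len(state.constraints):
        from .constraints import _residuals
        max_res = float(np.max(_residuals(pos, state.constraints, backend)))

    report = DriftReport(
        backend=backend.kind,
        n_atoms=state.n_atoms,
        dof=state.dof(),
        dt_fs=dt_fs,
        times_ps=times,
        e_total=etot,
        e_kinetic=np.asarray(ekin),
        e_potential=np.asarray(epots),
        slope_kcal_per_ns=slope,
        drift_kbt_per_ns_per_dof=drift,
        shake_max_residual=max_res,
        shake_mean_iterations=float(np.mean(shake_stats)) if shake_stats else 0.0,
        seed=seed,
    )
    report.final_state = state
    return report


STABILITY_CAP = 1e6


def drift_stability(report: DriftReport, reference: DriftReport) -> float:
    """Stability ratio ``|drift_ref| / |drift|``: the reference scores 1.00,
    noisier runs score below 1.  A zero measured drift is reported as the
    cap rather than a division error."""
    if report.drift_kbt_per_ns_per_dof is None or reference.drift_kbt_per_ns_per_dof is None:
        raise ValueError("both reports need a fitted drift")
    d = abs(report.drift_kbt_per_ns_per_dof)
    if d == 0.0:
        return STABILITY_CAP
    return min(abs(reference.drift_kbt_per_ns_per_dof) / d, STABILITY_CAP)
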