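"""Deterministic generators for the desk-scale test systems.

Everything is built programmatically from a recipe and a seed — no
topology files, no downloads.  Three families cover the behaviours the
coordinate-representation study needs:

* ``lj_fluid`` — Lennard-Jones particles (argon-like defaults) on a
  jittered lattice: the plain nonbonded stress case.
* ``water_box`` — rigid 3-site waters with TIP3P-like parameters and a
  full constraint network: the PME-free analogue of the solvent-box
  benchmark, the system whose NVE drift separates the backends.
* ``harmonic_chain`` — a bonded chain placed at a configurable offset from
  the box center, designed to probe the loss of bonded-term precision for
  atoms with large absolute coordinates (where FP32 spacing is coarsest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .box import BoxSpec
from .constraints import ConstraintSet
from .engine import SystemState, kinetic_temperature, remove_com_momentum
from .forcefield import KBOLTZ, KE_CONV, ForceField

__all__ = [
    "SystemRecipe",
    "RecipeError",
    "TIP3P",
    "build_lj_fluid",
    "build_water_box",
    "build_harmonic_chain",
]


class RecipeError(ValueError):
    """Recipe violates a physical sanity bound (density, box size...)."""


# TIP3P-like rigid water parameter set, version "tip3p-like-1".
# Only the oxygen carries Lennard-Jones parameters; geometry is the
# standard O-H 0.9572 A bond and 104.52 deg H-O-H angle.
TIP3P = {
    "name": "tip3p-like-1",
    "q_O": -0.834, "q_H": 0.417,
    "eps_O": 0.1521, "sigma_O": 3.1507,
    "mass_O": 15.9994, "mass_H": 1.008,
    "r_OH": 0.9572, "angle_HOH_deg": 104.52,
}

# argon-like LJ fluid defaults
LJ_FLUID = {"eps": 0.238, "sigma": 3.405, "mass": 39.948}

# generic alkane-like chain defaults
CHAIN = {"bond_r0": 1.53, "bond_k": 310.0, "angle_theta0_deg": 109.5,
         "angle_k": 40.0, "eps": 0.1094, "sigma": 3.4, "mass": 12.011}


@dataclass(frozen=True)
class SystemRecipe:
    """What to build: particle count, box, temperature and seed."""

    kind: str                       # lj_fluid | water_box | harmonic_chain
    n: int                          # particles or molecules
    lengths: tuple                  # box side lengths, Angstrom
    temperature: float = 300.0      # K
    seed: int = 0
    cutoff: float = 8.0
    offset: float = 0.0             # harmonic_chain: displacement from box center

    def box(self) -> BoxSpec:
        return BoxSpec(lengths=np.asarray(self.lengths, dtype=np.float64))


def hh_distance(r_oh: float, angle_deg: float) -> float:
    """H-H distance of a rigid 3-site water, by the law of cosines."""
    theta = math.radians(angle_deg)
    return math.sqrt(2.0 * r_oh**2 * (1.0 - math.cos(theta)))


def _lattice(n: int, lengths: np.ndarray) -> np.ndarray:
    """n sites of a simple cubic lattice filling a centered box."""
    per_side = math.ceil(n ** (1.0 / 3.0))
    spacing = lengths / per_side
    idx = np.arange(per_side)
    grid = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1).reshape(-1, 3)
    sites = (grid + 0.5) * spacing - lengths / 2.0
    return sites[:n]


def _mb_velocities(rng: np.random.Generator, masses: np.ndarray,
                   temperature: float) -> np.ndarray:
    sigma = np.sqrt(KBOLTZ * temperature / (masses * KE_CONV))
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def _thermalize(state: SystemState, rng: np.random.Generator,
                temperature: float) -> None:
    """Maxwell-Boltzmann draw, COM removal, exact rescale to the target T."""
    state.v = _mb_velocities(rng, state.masses, temperature)
    remove_com_momentum(state)
    t_now = kinetic_temperature(state)
    state.v *= math.sqrt(temperature / t_now)


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def build_lj_fluid(recipe: SystemRecipe) -> tuple[SystemState, ForceField]:
    """LJ particles on a perturbed lattice with Maxwell-Boltzmann velocities."""
    box = recipe.box()
    n = recipe.n
    if n < 1:
        raise RecipeError("need at least one particle")
    sigma = LJ_FLUID["sigma"]
    if n * sigma**3 > 0.9 * float(np.prod(box.lengths)):
        raise RecipeError("density too high: particles cannot fit the box")
    rng = np.random.default_rng(recipe.seed)
    x = _lattice(n, box.lengths)
    x += rng.uniform(-0.1, 0.1, size=x.shape)  # jitter <= 0.1 A per axis

    masses = np.full(n, LJ_FLUID["mass"])
    state = SystemState(x=x, v=np.zeros((n, 3)), masses=masses,
                        charges=np.zeros(n), box=box)
    if n > 1:
        _thermalize(state, rng, recipe.temperature)
    else:
        state.v = _mb_velocities(rng, masses, recipe.temperature)
    ff = ForceField(epsilon=np.full(n, LJ_FLUID["eps"]),
                    sigma=np.full(n, sigma),
                    cutoff=recipe.cutoff)
    return state, ff


def _water_template() -> np.ndarray:
    """One rigid water in its molecular frame, O at the origin."""
    r = TIP3P["r_OH"]
    half = math.radians(TIP3P["angle_HOH_deg"]) / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [r * math.cos(half), r * math.sin(half), 0.0],
        [r * math.cos(half), -r * math.sin(half), 0.0],
    ])


def build_water_box(recipe: SystemRecipe, relax_steps: int = 25,
                    tolerance: float = 1e-7) -> tuple[SystemState, ForceField]:
    """Rigid 3-site waters on a lattice with random orientations.

    Returns a state carrying the full constraint network (two O-H and one
    H-H distance per molecule) and a TIP3P-like force field with all
    intramolecular nonbonded pairs excluded.  A short steepest-descent
    relaxation (rigid geometry re-imposed after every move) removes any
    initial clashes.
    """
    box = recipe.box()
    n_mol = recipe.n
    if n_mol < 1:
        raise RecipeError("need at least one molecule")
    per_side = math.ceil(n_mol ** (1.0 / 3.0))
    if float(np.min(box.lengths)) / per_side < 2.4:
        raise RecipeError("box too small for the requested number of waters")

    rng = np.random.default_rng(recipe.seed)
    centers = _lattice(n_mol, box.lengths)
    rots = _random_rotations(rng, n_mol)
    template = _water_template()
    x = (rots @ template.T).transpose(0, 2, 1) + centers[:, None, :]
    x = x.reshape(-1, 3)

    n = 3 * n_mol
    masses = np.tile([TIP3P["mass_O"], TIP3P["mass_H"], TIP3P["mass_H"]], n_mol)
    charges = np.tile([TIP3P["q_O"], TIP3P["q_H"], TIP3P["q_H"]], n_mol)
    eps = np.tile([TIP3P["eps_O"], 0.0, 0.0], n_mol)
    sig = np.tile([TIP3P["sigma_O"], 1.0, 1.0], n_mol)

    base = 3 * np.arange(n_mol)[:, None]
    d_hh = hh_distance(TIP3P["r_OH"], TIP3P["angle_HOH_deg"])
    pairs = np.concatenate([base + [0, 1], base + [0, 2], base + [1, 2]])
    d0 = np.concatenate([np.full(n_mol, TIP3P["r_OH"]),
                         np.full(n_mol, TIP3P["r_OH"]),
                         np.full(n_mol, d_hh)])
    constraints = ConstraintSet(pairs=pairs, d0=d0, tolerance=tolerance)

    ff = ForceField(epsilon=eps, sigma=sig, cutoff=recipe.cutoff,
                    exclusions=pairs.copy())
    state = SystemState(x=x, v=np.zeros((n, 3)), masses=masses, charges=charges,
                        box=box, constraints=constraints)

    if relax_steps > 0:
        _relax(state, ff, relax_steps)
    _thermalize(state, rng, recipe.temperature)
    # velocities consistent with the rigid geometry
    from .backends import Fp64Backend
    from .constraints import rattle_velocities
    backend = Fp64Backend(box)
    pos = backend.from_cartesian(state.x)
    rattle_velocities(state.v, pos, constraints, backend, state.masses,
                      tolerance=1e-12)
    remove_com_momentum(state)
    t_now = kinetic_temperature(state)
    state.v *= math.sqrt(recipe.temperature / t_now)
    return state, ff


def _relax(state: SystemState, ff: ForceField, n_steps: int,
           max_move: float = 0.1) -> None:
    """Steepest descent with constraints re-imposed after every move."""
    from .backends import Fp64Backend
    from .constraints import shake
    from .engine import compute_forces

    backend = Fp64Backend(state.box)
    pos = backend.from_cartesian(state.x)
    for _ in range(n_steps):
        forces, _ = compute_forces(state, ff, backend, pos=pos)
        fmax = float(np.max(np.abs(forces)))
        if fmax < 1.0:
            break
        step = forces * (max_move / fmax)
        prev = np.array(pos)
        pos = backend.advance(pos, step)
        if state.constraints is not None:
            shake(pos, prev, state.constraints, backend, state.masses)
    state.x = backend.to_cartesian(pos)


def build_harmonic_chain(recipe: SystemRecipe) -> tuple[SystemState, ForceField]:
    """Linear bonded chain at a configurable offset from the box center.

    With ``offset`` near ``L/2`` the chain sits against the periodic edge,
    where FP32 coordinates are coarsest — the designed probe for bonded-term
    cancellation noise.  The construction itself is translation invariant.
    """
    box = recipe.box()
    n = recipe.n
    if n < 2:
        raise RecipeError("a chain needs at least two atoms")
    r0 = CHAIN["bond_r0"]
    if (n - 1) * r0 > 0.9 * float(box.lengths[0]):
        raise RecipeError("chain longer than the box")

    x = np.zeros((n, 3))
    x[:, 0] = (np.arange(n) - (n - 1) / 2.0) * r0 + recipe.offset

    bonds = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    angles = np.stack([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)], axis=1)
    # exclude 1-2 and 1-3 neighbours from the nonbonded sum
    excl = [(i, j) for i in range(n) for j in (i + 1, i + 2) if j < n]

    ff = ForceField(
        epsilon=np.full(n, CHAIN["eps"]), sigma=np.full(n, CHAIN["sigma"]),
        cutoff=recipe.cutoff,
        bonds=bonds, bond_k=np.full(n - 1, CHAIN["bond_k"]),
        bond_r0=np.full(n - 1, r0),
        angles=angles, angle_k=np.full(max(n - 2, 0), CHAIN["angle_k"]),
        angle_theta0=np.full(max(n - 2, 0), math.radians(CHAIN["angle_theta0_deg"])),
        exclusions=np.asarray(excl, dtype=np.int64).reshape(-1, 2),
    )
    rng = np.random.default_rng(recipe.seed)
    masses = np.full(n, CHAIN["mass"])
    state = SystemState(x=x, v=np.zeros((n, 3)), masses=masses,
                        charges=np.zeros(n), box=box)
    _thermalize(state, rng, recipe.temperature)
    return state, ff


def build(recipe: SystemRecipe):
    """Dispatch on ``recipe.kind``."""
    builders = {"lj_fluid": build_lj_fluid, "water_box": build_water_box,
                "harmonic_chain": build_harmonic_chain}
    if recipe.kind not in builders:
        raise RecipeError(f"unknown system kind {recipe.kind!r}")
    return builders[recipe.kind](recipe)
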