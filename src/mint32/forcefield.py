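"""Desk-scale force field: switched Lennard-Jones, shifted-force Coulomb,
harmonic bonds and angles.

The nonbonded terms are deliberately smooth at the cutoff (CHARMM-style
potential switching for LJ, shifted-force electrostatics) because the NVE
energy drift is used as a *diagnostic of coordinate-representation noise*:
truncation discontinuities would inject drift orders of magnitude larger
than the quantization signal under study.

Units throughout: Angstrom, femtosecond, kcal/mol, amu, elementary charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KBOLTZ = 0.0019872041          # kcal/(mol K)
COULOMB = 332.0637             # kcal Angstrom / (mol e^2)
ACC_CONV = 4.184e-4            # (kcal/mol/Angstrom)/amu -> Angstrom/fs^2
KE_CONV = 1.0 / ACC_CONV       # amu (Angstrom/fs)^2 -> kcal/mol
FIXED_FORCE_SCALE = 2.0**24    # fixed64 accumulator counts per kcal/mol/Angstrom
CLASH_FLOOR = 0.5              # Angstrom; below this a pair is a hard clash

__all__ = [
    "KBOLTZ",
    "COULOMB",
    "ACC_CONV",
    "KE_CONV",
    "ForceField",
    "ClashError",
]


class ClashError(RuntimeError):
    """Two atoms closer than the hard floor; names the offending pair."""

    def __init__(self, i: int, j: int, r: float):
        self.pair = (int(i), int(j))
        super().__init__(f"atoms {i} and {j} overlap at r = {r:.4f} A "
                         f"(floor {CLASH_FLOOR} A)")


@dataclass
class ForceField:
    """Per-atom nonbonded parameters plus bonded term lists.

    Lennard-Jones parameters are per atom and combined with
    Lorentz-Berthelot rules.  ``bonded_precision`` selects whether bond and
    angle geometry is evaluated in 32- or 64-bit floating point (the
    "Float Bond" / "Double Bond" variants); ``accumulator`` selects 64-bit
    float or 64-bit fixed-point force accumulation.
    """

    epsilon: np.ndarray                     # (N,) kcal/mol
    sigma: np.ndarray                       # (N,) Angstrom
    cutoff: float = 8.0
    switch_width: float = 1.0
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))      # kcal/mol/A^2
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))     # Angstrom
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))     # kcal/mol/rad^2
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))  # rad
    exclusions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bonded_precision: str = "fp64"          # "fp64" | "fp32"
    accumulator: str = "fp64"               # "fp64" | "fixed64"

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.exclusions = np.asarray(self.exclusions, dtype=np.int64).reshape(-1, 2)
        self.bond_k = np.asarray(self.bond_k, dtype=np.float64)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=np.float64)
        self.angle_k = np.asarray(self.angle_k, dtype=np.float64)
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=np.float64)
        if self.bonded_precision not in ("fp64", "fp32"):
            raise ValueError("bonded_precision must be 'fp64' or 'fp32'")
        if self.accumulator not in ("fp64", "fixed64"):
            raise ValueError("accumulator must be 'fp64' or 'fixed64'")
        if self.switch_width >= self.cutoff:
            raise ValueError("switch width must be smaller than the cutoff")

    def validate_box(self, lengths) -> None:
        if self.cutoff >= 0.5 * float(np.min(lengths)):
            raise ValueError(
                f"cutoff {self.cutoff} A must be < half the shortest box length "
                f"({0.5 * float(np.min(lengths)):.3f} A)")
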