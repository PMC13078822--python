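"""Coordinate backends: the representation contract the engine codes against.

Each backend owns the authoritative position state and exposes the same
operations — encode/decode, minimum-image pair displacement, drift update
and small-correction application — so that the integrator, force loop and
constraint solver are representation-agnostic.  Three backends mirror the
three precision models under study:

* ``Fp64Backend`` — reference: FP64 storage, branch-free FP64 minimum image.
* ``Fp32EmulatedBackend`` — mixed-precision production analogue: FP64
  authoritative storage, but a 32-bit working copy is taken for every
  displacement, and nonbonded pair arithmetic runs in FP32.  This narrows
  at the same stages as an SPFP-style engine and carries its coordinate
  quantization noise.
* ``Mint32Backend`` — signed 32-bit integer grid with self-wrapping
  minimum image; displacements are exact in integer space and converted
  per a :class:`~mint32.fixedpoint.ConversionPolicy`.
"""

from __future__ import annotations

import numpy as np

from .box import BoxSpec, ScaleFactors, make_scale_factors
from .fixedpoint import ConversionPolicy, decode, encode

__all__ = [
    "CoordinateBackend",
    "Fp64Backend",
    "Fp32EmulatedBackend",
    "Mint32Backend",
    "get_backend",
]


class CoordinateBackend:
    """Abstract representation contract.

    Positions handed to the engine are opaque arrays in the backend's
    native representation; only the backend interprets them.
    """

    kind: str

    def __init__(self, box: BoxSpec):
        self.box = box
        self.lengths = box.lengths

    # -- representation --------------------------------------------------
    def from_cartesian(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_cartesian(self, pos: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- geometry --------------------------------------------------------
    def pair_delta(self, pos: np.ndarray, ii, jj, bonded: bool = False) -> np.ndarray:
        """Minimum-image displacement ``pos[ii] - pos[jj]`` in Angstrom.

        ``bonded=True`` selects the (possibly higher-precision) path used
        for bonded terms and constraint geometry.
        """
        raise NotImplementedError

    # -- updates ---------------------------------------------------------
    def advance(self, pos: np.ndarray, dx: np.ndarray) -> np.ndarray:
        """Apply a Cartesian displacement (the integrator drift)."""
        raise NotImplementedError

    def apply_correction(self, pos: np.ndarray, indices, dx: np.ndarray) -> np.ndarray:
        """Add small Cartesian corrections (SHAKE) to selected atoms, in place.

        ``indices`` must not contain duplicates (guaranteed by the
        constraint solver's independent groups).
        """
        raise NotImplementedError

    @property
    def resolution(self) -> np.ndarray:
        """Per-axis representation grid spacing at the box edge, Angstrom."""
        raise NotImplementedError

    @property
    def constraint_resolution(self) -> np.ndarray:
        """Grid spacing seen by the constraint solver.

        Defaults to :attr:`resolution`; backends whose constraint path reads
        a higher-precision store override this.
        """
        return self.resolution


def _wrap_cartesian(x: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Branch-free wrap of centered Cartesian coordinates into [-L/2, L/2)."""
    return x - L * np.floor(x / L + 0.5)


class Fp64Backend(CoordinateBackend):
    kind = "fp64"

    def from_cartesian(self, x):
        return _wrap_cartesian(np.asarray(x, dtype=np.float64), self.lengths)

    def to_cartesian(self, pos):
        return np.array(pos, dtype=np.float64)

    def pair_delta(self, pos, ii, jj, bonded=False):
        d = pos[ii] - pos[jj]
        return d - self.lengths * np.rint(d / self.lengths)

    def advance(self, pos, dx):
        return _wrap_cartesian(pos + dx, self.lengths)

    def apply_correction(self, pos, indices, dx):
        pos[indices] += dx
        return pos

    @property
    def resolution(self):
        return np.spacing(self.lengths / 2.0)


class Fp32EmulatedBackend(CoordinateBackend):
    """Emulated FP32-coordinate engine.

    Mirrors the precision profile of a single-precision GPU engine at the
    stages that matter for coordinate noise: particle positions are
    quantized to the FP32 grid after every integration step (an
    irreversible narrowing — this is what makes FP32 coordinate
    quantization inject heat), and nonbonded pair displacements are formed
    in FP32 arithmetic with its cancellation behaviour.  Integration and
    constraint geometry use FP64 arithmetic on the (FP32-valued) master
    state, as mixed-precision engines do.
    """

    kind = "fp32_emulated"

    def __init__(self, box: BoxSpec, bonded_fp64: bool = True,
                 narrow_storage: bool = True):
        super().__init__(box)
        self.bonded_fp64 = bonded_fp64
        self.narrow_storage = narrow_storage
        self._L32 = self.lengths.astype(np.float32)

    def _narrow(self, x):
        if self.narrow_storage:
            return x.astype(np.float32).astype(np.float64)
        return x

    def from_cartesian(self, x):
        return self._narrow(_wrap_cartesian(np.asarray(x, dtype=np.float64),
                                            self.lengths))

    def to_cartesian(self, pos):
        return self._narrow(np.array(pos, dtype=np.float64))

    def pair_delta(self, pos, ii, jj, bonded=False):
        if bonded and self.bonded_fp64:
            # bonded/constraint path runs FP64 arithmetic on the master state
            d64 = pos[ii] - pos[jj]
            return d64 - self.lengths * np.rint(d64 / self.lengths)
        x32 = pos.astype(np.float32)
        d = x32[ii] - x32[jj]
        d = d - self._L32 * np.rint(d / self._L32).astype(np.float32)
        return d.astype(np.float64)

    def advance(self, pos, dx):
        # FP64 integration arithmetic, storage narrowed to the FP32 grid
        return self._narrow(_wrap_cartesian(pos + dx, self.lengths))

    def apply_correction(self, pos, indices, dx):
        pos[indices] += dx
        return pos

    @property
    def resolution(self):
        return np.spacing((self.lengths / 2.0).astype(np.float32)).astype(np.float64)

    @property
    def constraint_resolution(self):
        # constraints read the FP64 authoritative store (SPFP-style)
        return np.spacing(self.lengths / 2.0)


class Mint32Backend(CoordinateBackend):
    """Signed 32-bit integer grid with exact self-wrapping minimum image."""

    kind = "mint32"

    def __init__(self, box: BoxSpec,
                 nonbonded_policy: ConversionPolicy = ConversionPolicy.PROMOTE_FP64,
                 bonded_policy: ConversionPolicy = ConversionPolicy.PROMOTE_FP64):
        super().__init__(box)
        self.scale: ScaleFactors = make_scale_factors(box)
        self.nonbonded_policy = nonbonded_policy
        self.bonded_policy = bonded_policy
        self._inv64 = 1.0 / self.scale.S
        self._inv32 = np.float32(1.0) / self.scale.S.astype(np.float32)

    def from_cartesian(self, x):
        return encode(x, self.scale)

    def to_cartesian(self, pos):
        return decode(pos, self.scale)

    def pair_delta(self, pos, ii, jj, bonded=False):
        # exact self-wrapping integer subtraction (inline min_image_delta)
        d = pos[ii].astype(np.int64)
        d -= pos[jj]
        d = ((d + 2**31) & 0xFFFFFFFF) - 2**31
        policy = self.bonded_policy if bonded else self.nonbonded_policy
        if policy is ConversionPolicy.PROMOTE_FP64:
            return d.astype(np.float64) * self._inv64
        return (d.astype(np.float32) * self._inv32).astype(np.float64)

    def advance(self, pos, dx):
        # X(t+dt) = X(t) + round(v dt S): exact integer add, modular wrap
        step = np.rint(np.asarray(dx, dtype=np.float64) * self.scale.S).astype(np.int64)
        return (((pos.astype(np.int64) + step + 2**31) & 0xFFFFFFFF) - 2**31).astype(np.int32)

    def apply_correction(self, pos, indices, dx):
        # dX_corr = rint(dx_corr * S), exact modular add on the touched atoms
        step = np.rint(np.asarray(dx, dtype=np.float64) * self.scale.S).astype(np.int64)
        sub = pos[indices].astype(np.int64) + step
        pos[indices] = (((sub + 2**31) & 0xFFFFFFFF) - 2**31).astype(np.int32)
        return pos

    @property
    def resolution(self):
        return self.scale.inverse


def get_backend(kind: str, box: BoxSpec, **kwargs) -> CoordinateBackend:
    """Construct a backend by name: ``fp64``, ``fp32_emulated`` or ``mint32``."""
    table = {
        "fp64": Fp64Backend,
        "fp32_emulated": Fp32EmulatedBackend,
        "mint32": Mint32Backend,
    }
    try:
        cls = table[kind]
    except KeyError:
        raise ValueError(f"unknown backend {kind!r}; expected one of {sorted(table)}") from None
    return cls(box, **kwargs)
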