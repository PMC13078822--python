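"""MINT32 fixed-point coordinates: encoding, decoding and self-wrapping
minimum-image arithmetic.

The representation maps each periodic box length exactly onto the signed
32-bit integer cycle, ``X_alpha = round(x_alpha * S_alpha)`` with
``S_alpha = 2**32 / L_alpha``.  Because the periodic boundary coincides
with the integer overflow limit, the minimum-image displacement is the
plain 32-bit difference: wraparound modulo ``2**32`` *is* the periodic
wrap, with no branches and no cancellation.

Subtraction is implemented as exact arithmetic modulo ``2**32`` mapped
into ``[-2**31, 2**31 - 1]`` rather than by relying on hardware overflow,
which is bit-identical to two's-complement wraparound but portable.

Edge case: a separation of exactly half the box has two equally valid
minimum images; the modular reduction deterministically yields ``-2**31``,
whose negation is itself.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass

import numpy as np

from .box import TWO31, TWO32, BoxSpec, ScaleFactors

__all__ = [
    "ConversionPolicy",
    "encode",
    "decode",
    "min_image_delta",
    "delta_to_cartesian",
    "encode_fractional",
    "decode_fractional",
    "triclinic_delta",
    "quantization_stats",
    "QuantizationStats",
    "save_mint",
    "load_mint",
]

_MASK = TWO32 - 1


class ConversionPolicy(enum.Enum):
    """How an integer displacement is converted to a Cartesian float.

    ``DIRECT_FP32`` narrows the integer difference straight to a 32-bit
    float and scales in 32-bit arithmetic (the cheap production path; the
    24-bit significand reintroduces quantization steps for large
    separations — the "staircase effect").  ``PROMOTE_FP64`` promotes to a
    64-bit float before scaling, preserving the full integer difference.
    """

    DIRECT_FP32 = "direct_fp32"
    PROMOTE_FP64 = "promote_fp64"


def _wrap_signed(v) -> np.ndarray:
    """Reduce integers modulo 2**32 into the signed range, as int32."""
    v = np.asarray(v).astype(np.int64)
    return (((v + TWO31) & _MASK) - TWO31).astype(np.int32)


def encode(x, S: ScaleFactors) -> np.ndarray:
    """Encode Cartesian coordinates (Angstrom) as MINT32 integers.

    ``X_alpha = round_half_even(x_alpha * S_alpha)`` reduced modulo
    ``2**32`` into the signed range.  This is a total function on the
    reals: coordinates outside the primary box wrap onto it, which is the
    self-wrapping feature, not an error.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("coordinates must be finite")
    counts = np.rint(x * np.asarray(S.S))  # rint = round half to even
    # fmod keeps the cast to int64 in range for coordinates many boxes away
    return _wrap_signed(np.fmod(counts, TWO32))


def decode(X, S: ScaleFactors) -> np.ndarray:
    """Decode MINT32 integers to Cartesian Angstrom, in ``[-L/2, L/2)``."""
    X = np.asarray(X)
    return X.astype(np.float64) / np.asarray(S.S)


def min_image_delta(Xi, Xj) -> np.ndarray:
    """Exact minimum-image integer displacement ``Xi - Xj``.

    The difference is reduced modulo ``2**32`` into ``[-2**31, 2**31-1]``,
    which is bit-identical to letting the 32-bit subtraction overflow.  If
    the raw separation exceeds half the box along an axis, the wraparound
    lands on the correct periodic image automatically.
    """
    d = np.asarray(Xi, dtype=np.int64) - np.asarray(Xj, dtype=np.int64)
    return _wrap_signed(d)


def delta_to_cartesian(dX, S: ScaleFactors, policy: ConversionPolicy = ConversionPolicy.PROMOTE_FP64):
    """Convert an integer displacement to a Cartesian displacement (Angstrom).

    Under ``PROMOTE_FP64`` the conversion and scaling run in 64-bit and the
    result is returned in 64-bit.  Under ``DIRECT_FP32`` both happen in
    32-bit arithmetic, reproducing the staircase quantization of the cheap
    path; the result is float32.
    """
    dX = np.asarray(dX)
    if policy is ConversionPolicy.PROMOTE_FP64:
        return dX.astype(np.float64) / np.asarray(S.S, dtype=np.float64)
    Sinv32 = np.float32(1.0) / np.asarray(S.S).astype(np.float32)
    return dX.astype(np.float32) * Sinv32


def _wrap_fraction(u: np.ndarray) -> np.ndarray:
    """Wrap fractional coordinates into [-1/2, 1/2)."""
    u = u - np.floor(u + 0.5)
    # floor(u + 0.5) maps exactly-0.5 up, so +0.5 can only appear through
    # rounding; push it back to the lower edge for a half-open domain.
    u = np.where(u >= 0.5, u - 1.0, u)
    return u


def encode_fractional(r, box: BoxSpec) -> np.ndarray:
    """Encode Cartesian coordinates of a triclinic cell as fractional MINT32.

    ``u = H^-1 r`` wrapped into ``[-1/2, 1/2)``, then
    ``U_alpha = round_half_even(u_alpha * 2**32)`` with modular reduction.
    Orthorhombic ``H = diag(L)`` makes this identical to :func:`encode`.
    """
    H = box.require_cell()
    r = np.asarray(r, dtype=np.float64)
    if not np.all(np.isfinite(r)):
        raise ValueError("coordinates must be finite")
    u = _wrap_fraction(r @ np.linalg.inv(H).T)
    return _wrap_signed(np.rint(u * TWO32))


def decode_fractional(U, box: BoxSpec) -> np.ndarray:
    """Decode fractional MINT32 integers back to Cartesian Angstrom."""
    H = box.require_cell()
    u = np.asarray(U).astype(np.float64) / TWO32
    return u @ H.T


def triclinic_delta(Ui, Uj, box: BoxSpec,
                    policy: ConversionPolicy = ConversionPolicy.PROMOTE_FP64) -> np.ndarray:
    """Minimum-image Cartesian displacement between fractional positions.

    The fractional difference ``dU = Ui - Uj`` self-wraps along each
    lattice direction exactly as in the orthorhombic case; then
    ``du = dU / 2**32`` and ``dr = H du``.
    """
    H = box.require_cell()
    dU = min_image_delta(Ui, Uj)
    if policy is ConversionPolicy.PROMOTE_FP64:
        du = dU.astype(np.float64) / TWO32
        return du @ H.T
    du = dU.astype(np.float32) / np.float32(TWO32)
    return (du @ H.astype(np.float32).T).astype(np.float32)


@dataclass(frozen=True)
class QuantizationStats:
    mean: np.ndarray
    variance: np.ndarray
    predicted_variance: np.ndarray
    n: int


def quantization_stats(n: int, S: ScaleFactors, seed: int) -> QuantizationStats:
    """Empirical round-trip rounding-error statistics against the closed form.

    Draws ``n`` uniform positions per axis, encodes and decodes them, and
    returns the per-axis mean and variance of the error alongside the
    uniform-quantization prediction ``sigma^2 = 1 / (12 S^2)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = np.asarray(S.lengths)
    x = rng.uniform(-0.5, 0.5, size=(n, 3)) * L
    err = decode(encode(x, S), S) - x
    return QuantizationStats(
        mean=err.mean(axis=0),
        variance=err.var(axis=0),
        predicted_variance=1.0 / (12.0 * np.asarray(S.S) ** 2),
        n=n,
    )


# -- binary container ---------------------------------------------------------
#
# Little-endian layout: magic 'MI32', version u32, centered u8, pad 3 bytes,
# L (3 x f64), n_atoms u64, then n_atoms x 3 int32.

_MAGIC = b"MI32"
_HEADER = struct.Struct("<4sIB3x3dQ")


def save_mint(path, X: np.ndarray, box: BoxSpec) -> None:
    """Write a MINT32 position array with its box header, bit-exactly."""
    X = np.ascontiguousarray(X, dtype=np.int32).reshape(-1, 3)
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, 1, int(box.centered), *box.lengths, X.shape[0]))
        fh.write(X.astype("<i4").tobytes())


def load_mint(path) -> tuple[np.ndarray, BoxSpec]:
    """Read a MINT32 position array written by :func:`save_mint`."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER.size)
        magic, version, centered, Lx, Ly, Lz, n = _HEADER.unpack(header)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a MINT32 container")
        if version != 1:
            raise ValueError(f"{path}: unsupported container version {version}")
        data = np.frombuffer(fh.read(n * 12), dtype="<i4").reshape(n, 3)
    return data.astype(np.int32), BoxSpec.orthorhombic(Lx, Ly, Lz, centered=bool(centered))
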