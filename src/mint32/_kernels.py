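"""Compiled Gauss-Seidel constraint sweeps.

These kernels run the SHAKE/RATTLE iteration as a true sequential sweep in
ascending constraint order — the textbook algorithm — over either the
MINT32 integer store (corrections rounded to the grid every iteration) or
an FP64 Cartesian store.  They are numerically interchangeable with the
vectorised group sweep in :mod:`mint32.constraints`, which remains the
fallback when no JIT compiler is present.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap


_MASK = 0xFFFFFFFF
_TWO31 = 2**31


@njit(cache=False)
def _shake_int32(pos, prev, ii, jj, d0, inv_m, S, invS, tol, max_iter):
    nc = ii.shape[0]
    ref = np.empty((nc, 3))
    for c in range(nc):
        i, j = ii[c], jj[c]
        for k in range(3):
            d = (((np.int64(prev[i, k]) - np.int64(prev[j, k]) + _TWO31) & _MASK)
                 - _TWO31)
            ref[c, k] = d * invS[k]
    for sweep in range(1, max_iter + 1):
        worst = 0.0
        for c in range(nc):
            i, j = ii[c], jj[c]
            r2 = 0.0
            dot = 0.0
            for k in range(3):
                d = (((np.int64(pos[i, k]) - np.int64(pos[j, k]) + _TWO31) & _MASK)
                     - _TWO31)
                dx = d * invS[k]
                r2 += dx * dx
                dot += dx * ref[c, k]
            diff = r2 - d0[c] * d0[c]
            err = abs(diff) / (2.0 * d0[c])
            if err > worst:
                worst = err
            lam = diff / (2.0 * dot * (inv_m[i] + inv_m[j]))
            for k in range(3):
                corr = lam * ref[c, k]
                si = np.int64(np.rint(-corr * inv_m[i] * S[k]))
                sj = np.int64(np.rint(corr * inv_m[j] * S[k]))
                pos[i, k] = np.int32(((np.int64(pos[i, k]) + si + _TWO31) & _MASK) - _TWO31)
                pos[j, k] = np.int32(((np.int64(pos[j, k]) + sj + _TWO31) & _MASK) - _TWO31)
        if worst <= tol:
            ok = True
            for c in range(nc):
                i, j = ii[c], jj[c]
                r2 = 0.0
                for k in range(3):
                    d = (((np.int64(pos[i, k]) - np.int64(pos[j, k]) + _TWO31) & _MASK)
                         - _TWO31)
                    dx = d * invS[k]
                    r2 += dx * dx
                if abs(np.sqrt(r2) - d0[c]) > tol:
                    ok = False
                    break
            if ok:
                return sweep
    return -1


@njit(cache=False)
def _shake_f64(pos, prev, ii, jj, d0, inv_m, L, tol, max_iter):
    nc = ii.shape[0]
    ref = np.empty((nc, 3))
    for c in range(nc):
        i, j = ii[c], jj[c]
        for k in range(3):
            d = prev[i, k] - prev[j, k]
            ref[c, k] = d - L[k] * np.rint(d / L[k])
    for sweep in range(1, max_iter + 1):
        worst = 0.0
        for c in range(nc):
            i, j = ii[c], jj[c]
            r2 = 0.0
            dot = 0.0
            dxv = np.empty(3)
            for k in range(3):
                d = pos[i, k] - pos[j, k]
                d = d - L[k] * np.rint(d / L[k])
                dxv[k] = d
                r2 += d * d
                dot += d * ref[c, k]
            diff = r2 - d0[c] * d0[c]
            err = abs(diff) / (2.0 * d0[c])
            if err > worst:
                worst = err
            lam = diff / (2.0 * dot * (inv_m[i] + inv_m[j]))
            for k in range(3):
                corr = lam * ref[c, k]
                pos[i, k] -= corr * inv_m[i]
                pos[j, k] += corr * inv_m[j]
        if worst <= tol:
            ok = True
            for c in range(nc):
                i, j = ii[c], jj[c]
                r2 = 0.0
                for k in range(3):
                    d = pos[i, k] - pos[j, k]
                    d = d - L[k] * np.rint(d / L[k])
                    r2 += d * d
                if abs(np.sqrt(r2) - d0[c]) > tol:
                    ok = False
                    break
            if ok:
                return sweep
    return -1


@njit(cache=False)
def _rattle(vel, delta, ii, jj, inv_m, tol, max_iter):
    """Velocity projection given precomputed FP64 constraint vectors."""
    nc = ii.shape[0]
    for sweep in range(1, max_iter + 1):
        worst = 0.0
        for c in range(nc):
            i, j = ii[c], jj[c]
            proj = 0.0
            dsq = 0.0
            for k in range(3):
                d = delta[c, k]
                proj += (vel[i, k] - vel[j, k]) * d
                dsq += d * d
            err = abs(proj) / np.sqrt(dsq)
            if err > worst:
                worst = err
            lam = proj / (dsq * (inv_m[i] + inv_m[j]))
            for k in range(3):
                vel[i, k] -= lam * delta[c, k] * inv_m[i]
                vel[j, k] += lam * delta[c, k] * inv_m[j]
        if worst <= tol:
            return sweep
    return -1
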