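"""Plain XYZ coordinate file I/O (count line, comment line, element x y z)."""

from __future__ import annotations

import numpy as np

__all__ = ["read_xyz", "write_xyz", "XYZParseError"]


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries the offending line number."""


def read_xyz(path) -> tuple[list[str], np.ndarray, str]:
    """Read one frame: returns (element labels, (N, 3) coordinates, comment)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError(f"{path}:1: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}:1: expected an atom count, got {lines[0]!r}") from None
    if len(lines) < n + 2:
        raise XYZParseError(
            f"{path}: header promises {n} atoms but only {max(len(lines) - 2, 0)} records follow")
    comment = lines[1]
    labels: list[str] = []
    coords = np.empty((n, 3))
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}:{lineno}: expected 'element x y z'")
        labels.append(parts[0])
        try:
            coords[k] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}:{lineno}: non-numeric coordinate") from None
    return labels, coords, comment


def write_xyz(path, labels, coords, comment: str = "", append: bool = False) -> None:
    """Write one frame with 6 decimal places; append mode builds trajectories."""
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    if len(labels) != len(coords):
        raise ValueError("labels and coordinates differ in length")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{len(labels)}\n{comment}\n")
        for lab, (x, y, z) in zip(labels, coords):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
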