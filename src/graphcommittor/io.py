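"""Trajectory and table I/O.

Trajectories use an extended-XYZ dialect: per frame an atom-count line, a
comment line of ``key=value`` pairs (quoted values may contain spaces), then
one ``species x y z`` row per atom.  Recognized keys are ``cell``,
``bias_energy``, ``weight``, ``ndim``, ``reacting``, ``mobile``, ``masses``;
unknown keys are preserved verbatim in ``Configuration.extra`` and written
back on output.  Species are integer type codes.  Low-dimensional systems
are padded to three columns on disk; ``ndim`` restores the original shape.
"""

from __future__ import annotations

import csv
import hashlib
import json
import platform
from pathlib import Path

import numpy as np

from .systems import Configuration

__all__ = ["read_trajectory", "write_trajectory", "write_csv",
           "write_provenance", "TrajectoryFormatError"]


class TrajectoryFormatError(ValueError):
    """Malformed extended-XYZ input; the message names the offending line."""


def _format_value(v) -> str:
    if isinstance(v, (np.ndarray, list, tuple)):
        body = " ".join(f"{float(x):.12g}" for x in np.ravel(v))
        return f'"{body}"'
    if isinstance(v, (bool, np.bool_)):
        return "T" if v else "F"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.12g}"
    s = str(v)
    return f'"{s}"' if " " in s else s


def _parse_comment(line: str, lineno: int) -> dict:
    out: dict = {}
    i, n = 0, len(line)
    while i < n:
        while i < n and line[i].isspace():
            i += 1
        if i >= n:
            break
        eq = line.find("=", i)
        if eq < 0:
            raise TrajectoryFormatError(
                f"line {lineno}: expected key=value, got {line[i:]!r}")
        key = line[i:eq].strip()
        i = eq + 1
        if i < n and line[i] == '"':
            end = line.find('"', i + 1)
            if end < 0:
                raise TrajectoryFormatError(f"line {lineno}: unterminated quote")
            out[key] = line[i + 1:end]
            i = end + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            out[key] = line[i:j]
            i = j
    return out


def _floats(s: str) -> np.ndarray:
    return np.array([float(x) for x in s.split()])


def _bools(s: str) -> np.ndarray:
    return np.array([x in ("1", "T", "True") for x in s.split()])


def write_trajectory(frames, path) -> None:
    """Write frames as extended XYZ (3-column positions, zero padded)."""
    path = Path(path)
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_atoms}\n")
            keys = {
                "ndim": frame.ndim,
                "bias_energy": frame.bias_energy,
                "weight": frame.weight,
                "reacting": frame.reacting.astype(int),
                "mobile": frame.mobile.astype(int),
            }
            if frame.cell is not None:
                keys["cell"] = frame.cell
            if not np.all(frame.masses == 1.0):
                keys["masses"] = frame.masses
            for k, v in frame.extra.items():
                keys.setdefault(k, v)
            fh.write(" ".join(f"{k}={_format_value(v)}" for k, v in keys.items()))
            fh.write("\n")
            pos3 = np.zeros((frame.n_atoms, 3))
            pos3[:, : frame.ndim] = frame.positions
            for s, row in zip(frame.species, pos3):
                fh.write(f"{int(s)} {row[0]:.12f} {row[1]:.12f} {row[2]:.12f}\n")


_KNOWN_KEYS = {"ndim", "bias_energy", "weight", "reacting", "mobile",
               "masses", "cell"}


def read_trajectory(path) -> list[Configuration]:
    """Parse extended XYZ back into Configuration frames."""
    path = Path(path)
    frames: list[Configuration] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}") from None
        if i + 2 + n > len(lines):
            raise TrajectoryFormatError(
                f"line {i + 1}: frame truncated ({n} atoms declared, "
                f"{max(len(lines) - i - 2, 0)} rows left)")
        keys = _parse_comment(lines[i + 1], i + 2)
        species, pos = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"line {i + 3 + j}: expected 'species x y z', got "
                    f"{lines[i + 2 + j]!r}")
            species.append(int(parts[0]))
            pos.append([float(x) for x in parts[1:4]])
        ndim = int(keys.get("ndim", 3))
        positions = np.asarray(pos)[:, :ndim]
        reacting = (_bools(keys["reacting"]) if "reacting" in keys
                    else np.ones(n, dtype=bool))
        mobile = _bools(keys["mobile"]) if "mobile" in keys else None
        masses = _floats(keys["masses"]) if "masses" in keys else None
        cell = _floats(keys["cell"])[:ndim] if "cell" in keys else None
        extra = {k: v for k, v in keys.items() if k not in _KNOWN_KEYS}
        for num_key in ("z", "q", "index"):
            if num_key in extra:
                extra[num_key] = float(extra[num_key])
        frames.append(Configuration(
            positions, np.asarray(species), reacting, mobile=mobile,
            masses=masses, cell=cell,
            bias_energy=float(keys.get("bias_energy", 0.0)),
            weight=float(keys.get("weight", 1.0)),
            extra=extra,
        ))
        i += 2 + n
    return frames


def write_csv(path, rows, fieldnames=None) -> None:
    """Write a list of dicts as CSV (column order from the first row)."""
    rows = list(rows)
    if not rows:
        return
    fieldnames = fieldnames or list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)


def write_provenance(path, config_dict: dict, seeds: dict) -> None:
    """Record the run's config hash, seeds and versions next to its outputs."""
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    record = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
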