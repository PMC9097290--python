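"""Sequence and trajectory I/O helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .topology import CGStructure, bead_type_label, validate_sequence


def read_sequence(source: str | Path) -> str:
    """Sequence from a plain string, a plain-text file, or single-record FASTA."""
    path = Path(str(source))
    try:
        exists = path.is_file()
    except OSError:
        exists = False
    if not exists:
        return validate_sequence(str(source))
    text = path.read_text().strip()
    if text.startswith(">"):
        lines = text.splitlines()
        body = [l.strip() for l in lines[1:] if not l.startswith(">")]
        if any(l.startswith(">") for l in lines[1:]):
            raise ValueError("multi-record FASTA not supported: one duplex per file")
        return validate_sequence("".join(body))
    return validate_sequence("".join(text.split()))


def write_xyz(structure: CGStructure, frames: np.ndarray, path: str | Path,
              comment: str = "") -> Path:
    """Multi-frame XYZ export (element column = bead type label)."""
    path = Path(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    labels = [bead_type_label(b) for b in structure.beads]
    with open(path, "w") as fh:
        for f, x in enumerate(frames):
            fh.write(f"{len(labels)}\n{comment} frame {f}\n")
            for l, (px, py, pz) in zip(labels, x):
                fh.write(f"{l} {px:.6f} {py:.6f} {pz:.6f}\n")
    return path


def read_lammps_dump(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Frames and timesteps from a LAMMPS text dump (id x y z columns).

    Allows analysis of trajectories produced by an external LAMMPS run of
    the model.  Coordinates are sorted by atom id; scaled coordinates
    (xs, ys, zs) are not supported.
    """
    frames = []
    steps = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("ITEM: TIMESTEP"):
            steps.append(int(lines[i + 1]))
            i += 2
        elif lines[i].startswith("ITEM: NUMBER OF ATOMS"):
            n = int(lines[i + 1])
            i += 2
        elif lines[i].startswith("ITEM: ATOMS"):
            cols = lines[i].split()[2:]
            try:
                ci = cols.index("id")
                cx, cy, cz = (cols.index(c) for c in ("x", "y", "z"))
            except ValueError:
                raise ValueError(f"dump must contain id x y z columns, got {cols}")
            block = np.array([[float(v) for v in lines[i + 1 + k].split()]
                              for k in range(n)])
            order = np.argsort(block[:, ci])
            frames.append(block[order][:, [cx, cy, cz]])
            i += 1 + n
        else:
            i += 1
    if not frames:
        raise ValueError("no frames found in dump file")
    return np.array(frames), np.array(steps)
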