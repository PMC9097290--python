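"""Molecular builder: average starting structures and LAMMPS-format I/O.

A step library stores the mean coordinates of the 10 beads of each
dinucleotide step (four sugars, four bases, two phosphates).  A molecule is
assembled step by step: the first step contributes its coordinates verbatim;
every following step is rigidly superposed (Kabsch) onto the four beads it
shares with the growing structure (the two sugars and two bases of the
overlapping base pair), the shared beads are replaced by the mean of the two
aligned sets, and the remaining six beads are appended.  Assembly runs
strictly left to right — junction averaging is not associative, so the order
is part of the definition.  The finished molecule is translated so the first
strand-1 sugar sits at the origin and rotated so its axis lies along +z.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .constants import BEAD_MASSES
from .forcefield import ForceFieldParameters
from .fixtures import StepLibrary
from .topology import CGStructure, build_topology, bead_type_label, validate_sequence


class DegenerateGeometryError(ValueError):
    pass


def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition of ``Q`` onto ``P``.

    Returns ``(R, t, rmsd)`` with the proper rotation (det R = +1) and
    translation minimizing rmsd(P, R Q + t).  Reflections are never returned,
    so a mirror-image pair keeps a positive rmsd.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both have shape (m, 3)")
    if len(P) < 3:
        raise DegenerateGeometryError("need at least 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear sets leave a free rotation about the common axis
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, np.abs(Pc).max())) < 2 or \
       np.linalg.matrix_rank(Qc, tol=1e-9 * max(1.0, np.abs(Qc).max())) < 2:
        raise DegenerateGeometryError("collinear point set")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((P - (Q @ R.T + t)) ** 2, axis=1))))
    return R, t, rmsd


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking the unit vector ``axis`` to +z (Rodrigues)."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_average_structure(seq: str, lib: StepLibrary) -> CGStructure:
    """Assemble the sequence-dependent average structure from a step library.

    Deterministic: identical inputs yield bit-identical outputs.
    """
    seq = validate_sequence(seq)
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 base pairs")
    lib.validate()

    structure = build_topology(seq)
    coords = np.full((structure.n_beads, 3), np.nan)

    def mol_key(role, strand, local, i):
        # library local index 1|2 -> base-pair index i|i+1 of step i
        return (role, strand, i + local - 1)

    # first step placed verbatim
    first = lib[seq[0:2]]
    for (role, strand, local), xyz in first.items():
        coords[structure.bead_id(*mol_key(role, strand, local, 1))] = xyz

    shared_keys = [("S", 1, 2), ("S", 2, 2), ("B", 1, 2), ("B", 2, 2)]
    for i in range(2, n):  # steps (i, i+1), i >= 2
        entry = lib[seq[i - 1:i + 1]]
        # align the step's first base pair onto the already-placed pair i
        P = np.array([coords[structure.bead_id(role, strand, i)]
                      for role, strand, _ in [("S", 1, 1), ("S", 2, 1),
                                              ("B", 1, 1), ("B", 2, 1)]])
        Q = np.array([entry[("S", 1, 1)], entry[("S", 2, 1)],
                      entry[("B", 1, 1)], entry[("B", 2, 1)]])
        R, t, _ = kabsch_superpose(P, Q)
        moved = {k: v @ R.T + t for k, v in entry.items()}
        # overlapping beads: mean of the two aligned sets
        for role, strand, local in [("S", 1, 1), ("S", 2, 1), ("B", 1, 1), ("B", 2, 1)]:
            idx = structure.bead_id(role, strand, i)
            coords[idx] = 0.5 * (coords[idx] + moved[(role, strand, local)])
        # new beads of base pair i+1 (and the two linking phosphates)
        for role, strand, local in shared_keys + [("P", 1, 2), ("P", 2, 2)]:
            coords[structure.bead_id(*mol_key(role, strand, local, i))] = \
                moved[(role, strand, local)]

    if np.isnan(coords).any():
        raise RuntimeError("assembly left unplaced beads")

    # normalize: first strand-1 sugar at the origin, molecular axis along +z
    coords -= coords[structure.bead_id("S", 1, 1)]
    s1 = coords[structure.sugar_ids(1)]
    s2 = coords[structure.sugar_ids(2)]
    centers = 0.5 * (s1 + s2)
    centered = centers - centers.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    axis = Vt[0]
    if np.dot(axis, centers[-1] - centers[0]) < 0:
        axis = -axis
    Rz = _rotation_to_z(axis)
    coords = coords @ Rz.T
    coords -= coords[structure.bead_id("S", 1, 1)]
    return structure.with_coords(coords)


def map_atomistic_to_cg(groups) -> np.ndarray:
    """Map atomistic coordinates to beads at the geometric center of each moiety.

    ``groups`` is a sequence of (label, coords) pairs, one per bead, where
    ``coords`` holds the atom positions of that phosphate/sugar/base moiety.
    Returns the (n_beads, 3) array of unweighted centroids.
    """
    beads = []
    for label, atoms in groups:
        atoms = np.asarray(atoms, dtype=float)
        if atoms.size == 0:
            raise ValueError(f"empty atom group for moiety {label!r}")
        beads.append(atoms.reshape(-1, 3).mean(axis=0))
    return np.array(beads)


# ---------------------------------------------------------------------------
# LAMMPS data format
# ---------------------------------------------------------------------------

_ATOM_TYPE_ORDER = ["S", "P", "A", "C", "G", "T"]


def write_lammps_data(structure: CGStructure, params: ForceFieldParameters,
                      path: str | Path, box_pad: float = 50.0) -> Path:
    """Write an atom_style ``full`` data file plus a JSON topology manifest.

    One numeric bonded type is emitted per distinct (kind, class, context)
    parameter entry actually used; the manifest maps type ids back to labels
    and records the sequence, so the file round-trips losslessly through
    :func:`read_lammps_data`.  Bond/angle styles are ``harmonic`` (no 1/2
    prefactor, matching the model's convention) and dihedrals are ``charmm``
    with n = 1.
    """
    if structure.coords is None:
        raise ValueError("structure has no coordinates")
    path = Path(path)
    x = structure.coords

    atom_types = [l for l in _ATOM_TYPE_ORDER
                  if any(bead_type_label(b) == l for b in structure.beads)]
    atom_type_id = {l: i + 1 for i, l in enumerate(atom_types)}

    by_kind: dict[str, list] = {"bond": [], "angle": [], "dihedral": []}
    type_ids: dict[str, dict] = {"bond": {}, "angle": {}, "dihedral": {}}
    for t in structure.bonded_terms:
        ids = type_ids[t.kind]
        if t.key not in ids:
            ids[t.key] = len(ids) + 1
        by_kind[t.kind].append((ids[t.key], t.atoms))

    lo = x.min(axis=0) - box_pad
    hi = x.max(axis=0) + box_pad
    lines = ["duplexcg data file", ""]
    lines.append(f"{structure.n_beads} atoms")
    lines.append(f"{len(by_kind['bond'])} bonds")
    lines.append(f"{len(by_kind['angle'])} angles")
    lines.append(f"{len(by_kind['dihedral'])} dihedrals")
    lines.append("")
    lines.append(f"{len(atom_types)} atom types")
    lines.append(f"{len(type_ids['bond'])} bond types")
    lines.append(f"{len(type_ids['angle'])} angle types")
    lines.append(f"{len(type_ids['dihedral'])} dihedral types")
    lines.append("")
    for lab, axis in zip("xyz", range(3)):
        lines.append(f"{lo[axis]:.6f} {hi[axis]:.6f} {lab}lo {lab}hi")
    lines.append("")

    lines.append("Masses")
    lines.append("")
    for l in atom_types:
        lines.append(f"{atom_type_id[l]} {BEAD_MASSES[l]:.4f}  # {l}")
    lines.append("")

    def coeff_section(kind, title, fmt):
        if not type_ids[kind]:
            return
        lines.append(title)
        lines.append("")
        for key, tid in sorted(type_ids[kind].items(), key=lambda kv: kv[1]):
            term = params.get(*key)
            lines.append(f"{tid} {fmt(term)}  # {key[1]} {key[2]}")
        lines.append("")

    coeff_section("bond", "Bond Coeffs",
                  lambda t: f"{t.stiffness:.6f} {t.equilibrium:.6f}")
    coeff_section("angle", "Angle Coeffs",
                  lambda t: f"{t.stiffness:.6f} {math.degrees(t.equilibrium):.6f}")
    coeff_section("dihedral", "Dihedral Coeffs",
                  lambda t: f"{t.stiffness:.6f} 1 {round(math.degrees(t.equilibrium))} 0.0")

    lines.append("Atoms  # full")
    lines.append("")
    for i, bead in enumerate(structure.beads):
        q = params.q_phosphate if bead.role == "P" else 0.0
        tid = atom_type_id[bead_type_label(bead)]
        lines.append(f"{i + 1} 1 {tid} {q:.4f} "
                     f"{x[i, 0]:.10f} {x[i, 1]:.10f} {x[i, 2]:.10f}")
    lines.append("")

    for kind, title in [("bond", "Bonds"), ("angle", "Angles"),
                        ("dihedral", "Dihedrals")]:
        if not by_kind[kind]:
            continue
        lines.append(title)
        lines.append("")
        for row_id, (tid, atoms) in enumerate(by_kind[kind], start=1):
            atom_str = " ".join(str(a + 1) for a in atoms)
            lines.append(f"{row_id} {tid} {atom_str}")
        lines.append("")

    path.write_text("\n".join(lines) + "\n")

    manifest = {
        "sequence": structure.sequence,
        "atom_types": {str(i): l for l, i in atom_type_id.items()},
        "bonded_types": {
            kind: {str(tid): list(key) for key, tid in ids.items()}
            for kind, ids in type_ids.items()
        },
        "q_phosphate": params.q_phosphate,
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return path


def read_lammps_data(path: str | Path) -> CGStructure:
    """Read a data file written by :func:`write_lammps_data` back into a
    structure (topology rebuilt from the manifest's sequence, coordinates
    taken from the Atoms section)."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".manifest.json").read_text())
    structure = build_topology(manifest["sequence"])

    lines = path.read_text().splitlines()
    n_atoms = None
    coords = None
    section = None
    counts = {"Bonds": 0, "Angles": 0, "Dihedrals": 0}
    for raw in lines:
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if line.endswith("atoms"):
            n_atoms = int(line.split()[0])
            coords = np.zeros((n_atoms, 3))
            continue
        if line.split()[0] in ("Atoms", "Bonds", "Angles", "Dihedrals", "Masses",
                               "Bond", "Angle", "Dihedral", "Velocities"):
            section = raw.strip().split("#")[0].strip()
            continue
        if section == "Atoms":
            parts = line.split()
            coords[int(parts[0]) - 1] = [float(v) for v in parts[4:7]]
        elif section in counts:
            counts[section] += 1

    if coords is None or n_atoms != structure.n_beads:
        raise ValueError("data file does not match its manifest")
    expected = {"Bonds": "bond", "Angles": "angle", "Dihedrals": "dihedral"}
    for sec, kind in expected.items():
        n_expected = sum(1 for t in structure.bonded_terms if t.kind == kind)
        if counts[sec] != n_expected:
            raise ValueError(f"{sec} count {counts[sec]} != topology ({n_expected})")
    return structure.with_coords(coords)
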