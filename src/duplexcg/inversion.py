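"""Boltzmann inversion: harmonic parameters from coarse-grained ensembles.

Given a bead trajectory and its bonded topology, each (kind, class, context)
entry is parametrized from the pooled samples of its geometric coordinate:

* equilibrium values are ensemble means — arithmetic for bond lengths and
  angles, circular (mean resultant angle) for dihedrals, which avoids
  branch-cut artifacts near +-180 deg;
* stiffnesses reproduce the observed fluctuation size at temperature T:
  for the U = k x^2 convention k = kB T / (2 var), and for the periodic
  dihedral form (curvature k near the minimum) k = kB T / var.

The dihedral equilibrium is stored as phi0 = phi_min - 180 deg, matching the
energy model.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import CONSTANTS
from .forcefield import BondedTerm, ForceFieldParameters, wrap_angle
from .topology import CGStructure, CLASS_CONTEXT_TYPES


class MissingContextError(KeyError):
    pass


class DegenerateFluctuationError(ValueError):
    pass


def bond_series(frames: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bond lengths, shape (n_frames, n_terms)."""
    d = frames[:, idx[:, 1]] - frames[:, idx[:, 0]]
    return np.linalg.norm(d, axis=-1)


def angle_series(frames: np.ndarray, idx: np.ndarray) -> np.ndarray:
    rij = frames[:, idx[:, 0]] - frames[:, idx[:, 1]]
    rkj = frames[:, idx[:, 2]] - frames[:, idx[:, 1]]
    cos_t = np.sum(rij * rkj, axis=-1) / (
        np.linalg.norm(rij, axis=-1) * np.linalg.norm(rkj, axis=-1))
    return np.arccos(np.clip(cos_t, -1.0, 1.0))


def dihedral_series(frames: np.ndarray, idx: np.ndarray) -> np.ndarray:
    b1 = frames[:, idx[:, 1]] - frames[:, idx[:, 0]]
    b2 = frames[:, idx[:, 2]] - frames[:, idx[:, 1]]
    b3 = frames[:, idx[:, 3]] - frames[:, idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    return np.arctan2(np.sum(np.cross(n1, n2) * b2, axis=-1) / nb2,
                      np.sum(n1 * n2, axis=-1))


def circular_mean_var(phi: np.ndarray) -> tuple[float, float]:
    """Mean angle and variance of angular deviations about it.

    The mean is the resultant angle of the unit phasors; the variance is the
    ordinary variance of the deviations wrapped to (-pi, pi], which matches
    the harmonic-fluctuation variance for well-localized distributions.
    """
    mean = math.atan2(float(np.mean(np.sin(phi))), float(np.mean(np.cos(phi))))
    dev = wrap_angle(phi - mean)
    return mean, float(np.mean(dev**2))


_VARIANCE_FLOOR = 1e-10


def boltzmann_invert(frames: np.ndarray, topology: CGStructure,
                     T: float = 300.0,
                     sigma: dict | None = None,
                     q_phosphate: float = -0.6,
                     require_complete: bool = False) -> ForceFieldParameters:
    """Invert a bead trajectory into a harmonic parameter table.

    ``frames`` is (n_frames, n_beads, 3) in Angstrom.  Samples of every term
    instance are pooled per (kind, class, context).  ``require_complete``
    additionally demands that every context of every registered class was
    observed (useful when the trajectory is meant to parametrize the full
    model) and raises :class:`MissingContextError` otherwise.

    Raises :class:`DegenerateFluctuationError` if any pooled coordinate has
    (numerically) zero variance — a constant series cannot define a
    stiffness.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != topology.n_beads:
        raise ValueError("frames must be (n_frames, n_beads, 3) matching the topology")
    kBT = CONSTANTS.kB_kcal_mol * T

    groups: dict[tuple[str, str, str], list[int]] = {}
    by_kind: dict[str, list] = {"bond": [], "angle": [], "dihedral": []}
    for t in topology.bonded_terms:
        pos = len(by_kind[t.kind])
        by_kind[t.kind].append(t.atoms)
        groups.setdefault(t.key, []).append(pos)

    series = {}
    for kind, fn in (("bond", bond_series), ("angle", angle_series),
                     ("dihedral", dihedral_series)):
        if by_kind[kind]:
            series[kind] = fn(frames, np.array(by_kind[kind], dtype=np.intp))

    entries = []
    for (kind, label, context), cols in sorted(groups.items()):
        samples = series[kind][:, cols].ravel()
        if kind == "dihedral":
            mean, var = circular_mean_var(samples)
            if var < _VARIANCE_FLOOR:
                raise DegenerateFluctuationError(
                    f"{kind} {label}/{context}: variance below numerical floor")
            k = kBT / var
            phi0 = float(wrap_angle(mean - math.pi))
            entries.append(BondedTerm(kind, label, context, k, phi0))
        else:
            mean = float(np.mean(samples))
            var = float(np.var(samples))
            if var < _VARIANCE_FLOOR:
                raise DegenerateFluctuationError(
                    f"{kind} {label}/{context}: variance below numerical floor")
            k = kBT / (2.0 * var)
            entries.append(BondedTerm(kind, label, context, k, mean))

    if require_complete:
        from .forcefield import CONTEXT_SIZES, STEP_CONTEXTS

        observed = {(k, l, c) for (k, l, c) in groups}
        for (kind, label), ctype in CLASS_CONTEXT_TYPES.items():
            contexts = {"step": STEP_CONTEXTS, "base": tuple("ACGT"),
                        "pair": ("AT", "CG")}[ctype]
            for context in contexts:
                if (kind, label, context) not in observed:
                    raise MissingContextError(
                        f"{kind} {label}: context {context!r} never observed")

    return ForceFieldParameters.from_entries(
        entries, sigma=sigma or {}, q_phosphate=q_phosphate,
        context_types={}, validate=False)
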