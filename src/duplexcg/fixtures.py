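"""Synthetic structures and data sets with known ground truth.

These generators serve two roles: they are the oracles for the analysis
modules (a helix built with a prescribed rise/twist must be measured back
exactly), and they provide a self-consistent *toy* parameter set so that the
whole pipeline — builder, dynamics, analysis — runs without the published
force-field tables.  Every generator is deterministic given its arguments and
seed, and stores or returns its ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    BondedTerm,
    ForceFieldParameters,
    STEP_CONTEXTS,
    wrap_angle,
)
from .topology import (
    CGStructure,
    CLASS_CONTEXT_TYPES,
    build_topology,
    complement_base,
    validate_sequence,
)

#: shortest sequence whose duplex references every step context of every
#: step-dependent class away from the molecule ends (a de Bruijn covering of
#: the 16 dinucleotides, padded so terminal-only steps recur internally)
ALL_STEPS_SEQUENCE = "AACAGATCCGCTGGTTAT"

#: geometry of the toy B-DNA-like helix (Angstrom / degrees per step)
#: chosen so that no angle class sits near 0/180 deg (collinear geometries
#: make torsion forces singular) while bond lengths stay in the 3.5-5.5 A range
TOY_HELIX = dict(rise=3.4, twist=34.3, radius=9.4, sugar_radius=7.0,
                 base_radius=4.5, base_phase=35.0, groove_phase=154.0)


def random_sequence(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# ideal helix
# ---------------------------------------------------------------------------

def ideal_helix_coords(sequence: str, rise: float = 3.4, twist: float = 34.3,
                       radius: float = 9.4, sugar_radius: float = 7.0,
                       base_radius: float = 4.5, base_phase: float = 35.0,
                       groove_phase: float = 154.0,
                       mirror: bool = False) -> CGStructure:
    """Deterministic double-helical bead placement with known parameters.

    ``rise`` in Angstrom per step, ``twist`` in degrees per step, ``radius``
    is the phosphate radius (the fitted cylinder radius), ``groove_phase`` is
    the angular gap between the two sugars of a pair across the minor groove.
    ``mirror=True`` reflects x -> -x, producing the left-handed mirror image.

    The helix axis is z; by construction h-rise equals ``rise``, h-twist
    equals ``twist`` on every step and the best-fit cylinder through the
    phosphates has radius ``radius``.
    """
    sequence = validate_sequence(sequence)
    n = len(sequence)
    if n < 2:
        raise ValueError("need at least 2 base pairs")
    if rise <= 0 or radius <= 0 or sugar_radius <= 0 or base_radius < 0:
        raise ValueError("geometry parameters must be positive")
    omega = math.radians(twist)
    gamma = math.radians(groove_phase) / 2.0
    delta = math.radians(base_phase)

    structure = build_topology(sequence)
    coords = np.zeros((structure.n_beads, 3))

    def place(role, strand, i, r, ang, z):
        coords[structure.bead_id(role, strand, i)] = (r * math.cos(ang),
                                                      r * math.sin(ang), z)

    for i in range(1, n + 1):
        a = (i - 1) * omega
        z = (i - 1) * rise
        place("B", 1, i, base_radius, a + delta, z)
        place("B", 2, i, base_radius, a - delta, z)
        place("S", 1, i, sugar_radius, a + gamma, z)
        place("S", 2, i, sugar_radius, a - gamma, z)
        if i >= 2:
            place("P", 1, i, radius, a - omega / 2.0 + gamma, z - rise / 2.0)
            place("P", 2, i, radius, a - omega / 2.0 - gamma, z - rise / 2.0)

    if mirror:
        coords[:, 0] *= -1.0
    return structure.with_coords(coords)


def generate_ideal_helix(n: int, rise: float = 3.4, twist: float = 34.3,
                         radius: float = 9.4, groove_phase: float = 154.0,
                         sequence: str | None = None, **kw) -> CGStructure:
    """Ideal helix for ``n`` base pairs (poly-AT leading strand by default)."""
    if sequence is None:
        sequence = ("AT" * ((n + 1) // 2))[:n]
    if len(sequence) != n:
        raise ValueError("sequence length must equal n")
    return ideal_helix_coords(sequence, rise=rise, twist=twist, radius=radius,
                              groove_phase=groove_phase, **kw)


# ---------------------------------------------------------------------------
# toy force field and step library
# ---------------------------------------------------------------------------

TOY_SIGMA = {"S": 4.0, "P": 4.2, "A": 3.8, "C": 3.4, "G": 4.0, "T": 3.6}

#: stiffnesses chosen so the fastest normal mode of the assembled duplex has
#: a period of several hundred fs, comfortably resolved by the 20 fs step
_TOY_STIFFNESS = {"bond": 6.0, "angle": 12.0, "dihedral": 1.5}
#: Watson-Crick pairing stiffness: 2 vs 3 hydrogen bonds
_TOY_WC_STIFFNESS = {"AT": 2.0, "CG": 3.0}
_TOY_SB_STIFFNESS = 8.0


def _context_factor(context: str) -> float:
    """Deterministic mild (+-15%) sequence dependence of toy stiffnesses."""
    if context in STEP_CONTEXTS:
        rank = STEP_CONTEXTS.index(context)
        return 1.0 + 0.15 * ((rank % 4) - 1.5) / 1.5
    return 1.0


def toy_force_field() -> ForceFieldParameters:
    """Idealized parameter set covering the full class list (202 entries).

    Equilibrium values are measured on the ideal toy helix, so the helix is
    (up to the soft nonbonded terms) the ground state of the toy model;
    stiffnesses are idealized, with the BB-WC pairing constants in the 2:3
    AT:CG ratio of the hydrogen-bond counts.
    """
    ref = ideal_helix_coords(ALL_STEPS_SEQUENCE, **TOY_HELIX)
    x = ref.coords

    # measure one representative instance per (kind, class, context), away
    # from the ends when possible (the geometry is uniform, so any works)
    measured: dict[tuple[str, str, str], float] = {}
    for t in ref.bonded_terms:
        if t.key in measured:
            continue
        pts = x[list(t.atoms)]
        if t.kind == "bond":
            measured[t.key] = float(np.linalg.norm(pts[1] - pts[0]))
        elif t.kind == "angle":
            v1 = pts[0] - pts[1]
            v2 = pts[2] - pts[1]
            cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            measured[t.key] = float(np.arccos(np.clip(cosv, -1, 1)))
        else:
            measured[t.key] = _dihedral(pts)

    entries = []
    for (kind, label), ctype in CLASS_CONTEXT_TYPES.items():
        contexts = {"step": STEP_CONTEXTS, "base": tuple("ACGT"),
                    "pair": ("AT", "CG")}[ctype]
        for context in contexts:
            key = (kind, label, context)
            if key in measured:
                equil = measured[key]
            else:
                # geometry is context-independent: borrow any sibling context
                equil = next(v for (k2, l2, _), v in measured.items()
                             if (k2, l2) == (kind, label))
            if label == "BB-WC":
                k = _TOY_WC_STIFFNESS[context]
            elif label == "SB":
                k = _TOY_SB_STIFFNESS
            else:
                k = _TOY_STIFFNESS[kind] * _context_factor(context)
            if kind == "dihedral":
                equil = float(wrap_angle(equil - math.pi))  # phi0 = phi_min - 180
            entries.append(BondedTerm(kind, label, context, k, equil))

    return ForceFieldParameters.from_entries(
        entries, sigma=TOY_SIGMA, eps_wca=1.0, q_phosphate=-0.6,
        context_types=dict(CLASS_CONTEXT_TYPES))


def _dihedral(p: np.ndarray) -> float:
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    return float(math.atan2(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)),
                            np.dot(n1, n2)))


@dataclass
class StepLibrary:
    """Mean coordinates of the 10 beads of each dinucleotide step.

    Keys of each entry: (role, strand, local index 1|2); phosphates exist at
    local index 2 only (one per strand).
    """

    steps: dict[str, dict[tuple[str, int, int], np.ndarray]] = field(default_factory=dict)

    def __contains__(self, step: str) -> bool:
        return step in self.steps

    def __getitem__(self, step: str) -> dict[tuple[str, int, int], np.ndarray]:
        try:
            return self.steps[step]
        except KeyError:
            raise KeyError(f"step library is missing step {step!r}") from None

    def validate(self) -> None:
        missing = [s for s in STEP_CONTEXTS if s not in self.steps]
        if missing:
            raise ValueError(f"incomplete step library, missing {missing}")


def toy_step_library(**helix_kw) -> StepLibrary:
    """Step library cut from the ideal toy helix (all steps share the same
    idealized geometry, so the assembled average structure is an ideal helix)."""
    params = dict(TOY_HELIX)
    params.update(helix_kw)
    lib = StepLibrary()
    for step in STEP_CONTEXTS:
        frag = ideal_helix_coords(step, **params)
        entry = {}
        for local in (1, 2):
            for strand in (1, 2):
                entry[("S", strand, local)] = frag.coords[frag.bead_id("S", strand, local)]
                entry[("B", strand, local)] = frag.coords[frag.bead_id("B", strand, local)]
                if local == 2:
                    entry[("P", strand, 2)] = frag.coords[frag.bead_id("P", strand, 2)]
        lib.steps[step] = entry
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# worm-like chains
# ---------------------------------------------------------------------------

def generate_wlc_ensemble(n_chains: int, n_segments: int, segment_l: float,
                          l_p: float, seed: int):
    """Discrete worm-like chains with exact exponential tangent correlations.

    Each successive tangent is rotated by the fixed polar angle whose cosine
    is exp(-segment_l / l_p), with a uniform azimuth, so
    <t_i . t_j> = exp(-|i-j| segment_l / l_p) holds exactly for the returned
    unit tangents.  Returns ``(positions, tangents)`` with shapes
    (n_chains, n_segments+1, 3) and (n_chains, n_segments, 3), in the same
    length unit as ``segment_l``.
    """
    if l_p <= 0 or segment_l <= 0:
        raise ValueError("l_p and segment_l must be positive")
    rng = np.random.default_rng(seed)
    cos_t = math.exp(-segment_l / l_p)
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t**2))
    tangents = np.zeros((n_chains, n_segments, 3))
    t = np.tile([0.0, 0.0, 1.0], (n_chains, 1))
    for k in range(n_segments):
        tangents[:, k] = t
        psi = rng.uniform(0.0, 2.0 * math.pi, size=n_chains)
        # orthonormal frame perpendicular to t
        helper = np.where(np.abs(t[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        e1 = np.cross(t, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(t, e1)
        t = cos_t * t + sin_t * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    positions = np.concatenate(
        [np.zeros((n_chains, 1, 3)), np.cumsum(tangents * segment_l, axis=1)], axis=1)
    return positions, tangents


# ---------------------------------------------------------------------------
# elastic-rod response tables
# ---------------------------------------------------------------------------

def generate_rod_response(S_eff: float, C: float, g: float, L0: float,
                          theta0: float, forces, torques, noise: float = 0.0,
                          seed: int = 0):
    """Extension/twist tables from the linear elastic-rod equilibrium.

    For each (f, tau) combination:
        dL     = (L0/S_eff) f - (g L0 / (C S_eff)) tau
        dtheta = -(g L0 / (C S_eff)) f + (L0/C) (1 + g^2/(C S_eff)) tau
    plus Gaussian noise of standard deviation ``noise`` (absolute, applied to
    both dL in nm and dtheta in rad).  Units: pN, pN nm, nm, rad.

    Returns a pandas DataFrame with columns f_pN, tau_pN_nm, L_nm, theta_rad,
    dL_nm, dtheta_rad and attrs carrying the ground truth.
    """
    import pandas as pd

    if S_eff <= 0 or C <= 0 or L0 <= 0:
        raise ValueError("S_eff, C and L0 must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for f in np.atleast_1d(forces):
        for tau in np.atleast_1d(torques):
            dL = L0 / S_eff * f - g * L0 / (C * S_eff) * tau
            dth = -g * L0 / (C * S_eff) * f + L0 / C * (1.0 + g**2 / (C * S_eff)) * tau
            if noise > 0:
                dL += rng.normal(0.0, noise)
                dth += rng.normal(0.0, noise)
            rows.append(dict(f_pN=float(f), tau_pN_nm=float(tau),
                             L_nm=L0 + dL, theta_rad=theta0 + dth,
                             dL_nm=dL, dtheta_rad=dth))
    frame = pd.DataFrame(rows)
    frame.attrs["ground_truth"] = dict(S_eff=S_eff, C=C, g=g, L0=L0,
                                       theta0=theta0, noise=noise, seed=seed)
    return frame
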