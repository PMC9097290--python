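"""Energy model: bonded potentials, WCA excluded volume, Debye-Hueckel electrostatics.

Bonded interactions come in three kinds.  Bonds and angles are harmonic
without the 1/2 prefactor,

    U_bond(r)      = k (r - r0)^2
    U_angle(theta) = k (theta - theta0)^2

matching the LAMMPS ``harmonic`` styles, so the Boltzmann relation between a
stiffness and the thermal variance of its coordinate is k = kB*T / (2 var).
Dihedrals use the periodic form

    U_dihedral(phi) = k [1 + cos(phi - phi0)],   phi0 = phi_min - 180 deg,

whose global minimum sits at the equilibrium dihedral phi_min.

Each parametrized interaction belongs to a *class* (for example the backbone
bond 5'-SP-3', or the Watson-Crick pairing bond BB-WC) and carries a sequence
context: step-dependent classes have one entry per dinucleotide step (16),
base-dependent classes one per base (4) and Watson-Crick-pair-dependent
classes one per pair (2).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import CONSTANTS, PhysicalConstants

KINDS = ("bond", "angle", "dihedral")

STEP_CONTEXTS = tuple(a + b for a in "ACGT" for b in "ACGT")
BASE_CONTEXTS = ("A", "C", "G", "T")
PAIR_CONTEXTS = ("AT", "CG")

#: context cardinality demanded of each context type
CONTEXT_SIZES = {"step": 16, "base": 4, "pair": 2}


class MissingParameterError(KeyError):
    """A bonded term enumerated by the topology has no parameter entry."""


@dataclass(frozen=True)
class BondedTerm:
    """One parametrized bonded interaction.

    ``stiffness`` is k_bond (kcal/mol/A^2), k_angle (kcal/mol/rad^2) or
    k_dihedral (kcal/mol); ``equilibrium`` is r0 (A), theta0 (rad) or phi0
    (rad).  For dihedrals the minimum of the potential lies at
    ``equilibrium + pi``.
    """

    kind: str
    class_label: str
    context: str
    stiffness: float
    equilibrium: float

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown bonded kind {self.kind!r}")
        if self.stiffness <= 0:
            raise ValueError(f"nonpositive stiffness for {self.class_label}/{self.context}")
        if self.kind == "angle" and not (0.0 < self.equilibrium < math.pi):
            raise ValueError("angle equilibrium must lie in (0, pi)")
        if self.kind == "dihedral" and not (-math.pi < self.equilibrium <= math.pi):
            raise ValueError("dihedral equilibrium must lie in (-pi, pi]")

    @property
    def phi_min(self) -> float:
        """Equilibrium dihedral angle phi_min = phi0 + pi, wrapped to (-pi, pi]."""
        if self.kind != "dihedral":
            raise ValueError("phi_min defined only for dihedrals")
        return wrap_angle(self.equilibrium + math.pi)


def wrap_angle(phi):
    """Wrap an angle (rad) to (-pi, pi]."""
    wrapped = np.asarray((-phi + math.pi) % (2.0 * math.pi))
    return -(wrapped - math.pi)


def bond_energy(r, term: BondedTerm):
    """Harmonic bond energy U = k (r - r0)^2 in kcal/mol; ``r`` in Angstrom."""
    if term.kind != "bond":
        raise ValueError("term is not a bond")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    return term.stiffness * (r - term.equilibrium) ** 2


def angle_energy(theta, term: BondedTerm):
    """Harmonic angle energy U = k (theta - theta0)^2 in kcal/mol; ``theta`` in rad."""
    if term.kind != "angle":
        raise ValueError("term is not an angle")
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > math.pi)):
        raise ValueError("angle must lie in [0, pi]")
    return term.stiffness * (theta - term.equilibrium) ** 2


def dihedral_energy(phi, term: BondedTerm):
    """Periodic dihedral energy U = k [1 + cos(phi - phi0)] in kcal/mol."""
    if term.kind != "dihedral":
        raise ValueError("term is not a dihedral")
    phi = np.asarray(phi, dtype=float)
    return term.stiffness * (1.0 + np.cos(phi - term.equilibrium))


def wca_energy(r, sigma: float, eps: float = 1.0):
    """Weeks-Chandler-Andersen repulsion: shifted LJ truncated at 2^(1/6) sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    cutoff = 2.0 ** (1.0 / 6.0) * sigma
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6) + eps
    return np.where(r < cutoff, u, 0.0)


def debye_length(T: float, I: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Debye screening length in nm for temperature ``T`` (K) and ionic strength ``I`` (mM).

    l_D = sqrt(eps0 epsr kB T / (2 NA e0^2 I)); ionic strength in mM equals
    mol/m^3, so the expression is evaluated directly in SI units.
    """
    if T <= 0 or I <= 0:
        raise ValueError("temperature and ionic strength must be positive")
    c = constants
    lD_m = math.sqrt(c.eps0 * c.epsr * c.kB_J * T / (2.0 * c.NA * c.e0**2 * I))
    return lD_m * 1e9


def debye_huckel_energy(r, qi: float, qj: float, l_D: float,
                        constants: PhysicalConstants = CONSTANTS):
    """Screened Coulomb energy in kcal/mol.

    ``r`` in Angstrom, charges in units of e0, ``l_D`` in nm.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    lD_A = l_D * 10.0
    return constants.coulomb_kcal_A * qi * qj / (constants.epsr * r) * np.exp(-r / lD_A)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

def canonical_pair(base: str) -> str:
    """Watson-Crick pair label ('AT' or 'CG') for a base."""
    return "AT" if base in "AT" else "CG"


@dataclass
class ForceFieldParameters:
    """Complete parameter set: bonded table, WCA diameters and charge model.

    ``bonded`` maps ``(kind, class_label, context)`` to a :class:`BondedTerm`.
    ``sigma`` maps a bead role ('S', 'P') or base letter to the WCA diameter
    in Angstrom.  Phosphate beads carry the effective reduced charge
    ``q_phosphate`` (in e0 units, -0.6 by default) to account for counterion
    condensation.
    """

    bonded: dict[tuple[str, str, str], BondedTerm]
    sigma: dict[str, float]
    eps_wca: float = 1.0
    q_phosphate: float = -0.6
    context_types: dict[tuple[str, str], str] = field(default_factory=dict)

    def get(self, kind: str, class_label: str, context: str) -> BondedTerm:
        try:
            return self.bonded[(kind, class_label, context)]
        except KeyError:
            raise MissingParameterError(
                f"no parameter entry for {kind} {class_label} in context {context!r}"
            ) from None

    def n_entries(self) -> int:
        return len(self.bonded)

    def validate(self) -> None:
        """Check the 16/4/2 context cardinalities class by class."""
        by_class: dict[tuple[str, str], set[str]] = {}
        for (kind, label, context) in self.bonded:
            by_class.setdefault((kind, label), set()).add(context)
        for key, contexts in by_class.items():
            ctype = self.context_types.get(key)
            if ctype is None:
                continue
            expected = CONTEXT_SIZES[ctype]
            if len(contexts) != expected:
                raise ValueError(
                    f"{key[0]} {key[1]}: {len(contexts)} contexts, expected {expected}"
                )

    # -- serialization ------------------------------------------------------

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "kind": t.kind,
                "class_label": t.class_label,
                "context": t.context,
                "stiffness": t.stiffness,
                "equilibrium": t.equilibrium,
            }
            for t in self.bonded.values()
        ]
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "sigma": self.sigma,
            "eps_wca": self.eps_wca,
            "q_phosphate": self.q_phosphate,
            "context_types": {f"{k}:{l}": v for (k, l), v in self.context_types.items()},
        }
        if path.suffix == ".json":
            payload = dict(meta)
            payload["bonded"] = [
                [t.kind, t.class_label, t.context, t.stiffness, t.equilibrium]
                for t in self.bonded.values()
            ]
            path.write_text(json.dumps(payload, indent=1))
        else:
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["kind", "class_label", "context", "stiffness", "equilibrium"])
                for t in self.bonded.values():
                    writer.writerow([t.kind, t.class_label, t.context, t.stiffness, t.equilibrium])
            path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_entries(cls, entries: Iterable[BondedTerm], sigma: Mapping[str, float],
                     eps_wca: float = 1.0, q_phosphate: float = -0.6,
                     context_types: Mapping[tuple[str, str], str] | None = None,
                     validate: bool = True) -> "ForceFieldParameters":
        bonded = {(t.kind, t.class_label, t.context): t for t in entries}
        ff = cls(bonded=bonded, sigma=dict(sigma), eps_wca=eps_wca,
                 q_phosphate=q_phosphate, context_types=dict(context_types or {}))
        if validate:
            ff.validate()
        return ff

    @classmethod
    def load(cls, path: str | Path) -> "ForceFieldParameters":
        path = Path(path)
        if path.suffix == ".json":
            payload = json.loads(path.read_text())
            entries = [BondedTerm(k, l, c, float(s), float(e))
                       for k, l, c, s, e in payload["bonded"]]
            meta = payload
        else:
            entries = []
            with open(path) as fh:
                for row in csv.DictReader(fh):
                    entries.append(BondedTerm(row["kind"], row["class_label"], row["context"],
                                              float(row["stiffness"]), float(row["equilibrium"])))
            meta_path = path.with_suffix(path.suffix + ".meta.json")
            meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        context_types = {}
        for key, v in (meta.get("context_types") or {}).items():
            kind, label = key.split(":", 1)
            context_types[(kind, label)] = v
        return cls.from_entries(
            entries,
            sigma=meta.get("sigma", {}),
            eps_wca=float(meta.get("eps_wca", 1.0)),
            q_phosphate=float(meta.get("q_phosphate", -0.6)),
            context_types=context_types,
            validate=bool(context_types),
        )
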