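"""Vectorized energy and force evaluation for a parametrized duplex.

The bonded topology is compiled once into flat index/parameter arrays; the
nonbonded part (WCA excluded volume between all bead pairs, Debye-Hueckel
repulsion between phosphates) uses a KD-tree neighbor list with a skin,
rebuilt when any bead has moved more than half the skin since the last build.
Bead pairs that share any bonded term are excluded from both nonbonded
interactions, so bonded and nonbonded contributions are never double counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import CONSTANTS
from .forcefield import ForceFieldParameters, debye_length
from .topology import CGStructure, bead_type_label

_WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass
class NonbondedConfig:
    T: float = 300.0
    I: float = 150.0           # ionic strength, mM
    dh_cutoff_factor: float = 5.0
    skin: float = 4.0          # neighbor-list skin, Angstrom


class EnergyModel:
    """Compiled energy/force evaluator for one structure + parameter set."""

    def __init__(self, structure: CGStructure, params: ForceFieldParameters,
                 T: float = 300.0, I: float = 150.0,
                 dh_cutoff_factor: float = 5.0, skin: float = 4.0):
        self.structure = structure
        self.params = params
        self.T = T
        self.I = I
        n_beads = structure.n_beads

        bonds, angles, dihedrals = [], [], []
        for t in structure.bonded_terms:
            term = params.get(*t.key)
            if t.kind == "bond":
                bonds.append((*t.atoms, term.stiffness, term.equilibrium))
            elif t.kind == "angle":
                angles.append((*t.atoms, term.stiffness, term.equilibrium))
            else:
                dihedrals.append((*t.atoms, term.stiffness, term.equilibrium))

        def pack(rows, n_idx):
            if not rows:
                return np.empty((0, n_idx), dtype=np.intp), np.empty(0), np.empty(0)
            arr = np.array(rows, dtype=float)
            return arr[:, :n_idx].astype(np.intp), arr[:, n_idx], arr[:, n_idx + 1]

        self.bond_idx, self.bond_k, self.bond_r0 = pack(bonds, 2)
        self.angle_idx, self.angle_k, self.angle_t0 = pack(angles, 3)
        self.dih_idx, self.dih_k, self.dih_p0 = pack(dihedrals, 4)

        # per-bead WCA sigma and charge
        labels = [bead_type_label(b) for b in structure.beads]
        self.sigma = np.array([params.sigma[l] for l in labels])
        self.charge = np.array([params.q_phosphate if b.role == "P" else 0.0
                                for b in structure.beads])
        self.eps_wca = params.eps_wca

        self.l_D_A = debye_length(T, I) * 10.0
        self.dh_cut = dh_cutoff_factor * self.l_D_A
        self.dh_prefactor = CONSTANTS.coulomb_kcal_A / CONSTANTS.epsr
        self.skin = skin
        self.wca_cut_max = _WCA_CUT * self.sigma.max()
        self.list_cut = max(self.dh_cut, self.wca_cut_max) + self.skin

        # exclusions: any pair of beads sharing a bonded term
        excl = set()
        for t in structure.bonded_terms:
            atoms = t.atoms
            for a in range(len(atoms)):
                for b in range(a + 1, len(atoms)):
                    i, j = sorted((atoms[a], atoms[b]))
                    excl.add(i * n_beads + j)
        self._excl_codes = np.array(sorted(excl), dtype=np.int64)
        self._n_beads = n_beads
        self._pairs = None
        self._ref_coords = None

    # -- neighbor list ------------------------------------------------------

    def _rebuild_pairs(self, coords: np.ndarray) -> None:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(self.list_cut, output_type="ndarray")
        if pairs.size:
            codes = pairs[:, 0].astype(np.int64) * self._n_beads + pairs[:, 1]
            keep = ~np.isin(codes, self._excl_codes, assume_unique=False)
            pairs = pairs[keep]
        self._pairs = pairs
        self._pair_sigma = 0.5 * (self.sigma[pairs[:, 0]] + self.sigma[pairs[:, 1]]) \
            if pairs.size else np.empty(0)
        self._pair_qq = self.charge[pairs[:, 0]] * self.charge[pairs[:, 1]] \
            if pairs.size else np.empty(0)
        self._ref_coords = coords.copy()

    def _ensure_pairs(self, coords: np.ndarray) -> None:
        if self._pairs is None:
            self._rebuild_pairs(coords)
            return
        disp2 = np.max(np.sum((coords - self._ref_coords) ** 2, axis=1))
        if disp2 > (0.5 * self.skin) ** 2:
            self._rebuild_pairs(coords)

    # -- evaluation ---------------------------------------------------------

    def compute(self, coords: np.ndarray, brute_force_pairs: bool = False):
        """Return (energy kcal/mol, forces kcal/mol/A, shape (N, 3))."""
        coords = np.asarray(coords, dtype=float)
        forces = np.zeros_like(coords)
        energy = 0.0
        energy += self._bonds(coords, forces)
        energy += self._angles(coords, forces)
        energy += self._dihedrals(coords, forces)
        energy += self._nonbonded(coords, forces, brute_force_pairs)
        return energy, forces

    def _bonds(self, x, f):
        if not len(self.bond_idx):
            return 0.0
        i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
        d = x[j] - x[i]
        r = np.linalg.norm(d, axis=1)
        dr = r - self.bond_r0
        coef = (2.0 * self.bond_k * dr / r)[:, None] * d
        np.add.at(f, i, coef)
        np.add.at(f, j, -coef)
        return float(np.sum(self.bond_k * dr * dr))

    def _angles(self, x, f):
        if not len(self.angle_idx):
            return 0.0
        i, j, k = (self.angle_idx[:, c] for c in range(3))
        rij = x[i] - x[j]
        rkj = x[k] - x[j]
        nij = np.linalg.norm(rij, axis=1)
        nkj = np.linalg.norm(rkj, axis=1)
        cos_t = np.clip(np.sum(rij * rkj, axis=1) / (nij * nkj), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
        dU = 2.0 * self.angle_k * (theta - self.angle_t0)
        # dtheta/dxi and dtheta/dxk
        uij = rij / nij[:, None]
        ukj = rkj / nkj[:, None]
        gi = (cos_t[:, None] * uij - ukj) / (nij * sin_t)[:, None]
        gk = (cos_t[:, None] * ukj - uij) / (nkj * sin_t)[:, None]
        fi = -dU[:, None] * gi
        fk = -dU[:, None] * gk
        np.add.at(f, i, fi)
        np.add.at(f, k, fk)
        np.add.at(f, j, -(fi + fk))
        return float(np.sum(self.angle_k * (theta - self.angle_t0) ** 2))

    def _dihedrals(self, x, f):
        if not len(self.dih_idx):
            return 0.0
        i, j, k, l = (self.dih_idx[:, c] for c in range(4))
        b1 = x[j] - x[i]
        b2 = x[k] - x[j]
        b3 = x[l] - x[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        phi = np.arctan2(np.sum(np.cross(n1, n2) * b2, axis=1) / nb2,
                         np.sum(n1 * n2, axis=1))
        energy = float(np.sum(self.dih_k * (1.0 + np.cos(phi - self.dih_p0))))
        dU = -self.dih_k * np.sin(phi - self.dih_p0)
        # the torsion gradient diverges when three beads become collinear
        # (|n| -> 0); floor the denominators to cap the force in that
        # measure-zero region instead of letting the integrator blow up
        floor1 = 1e-4 * np.sum(b1 * b1, axis=1) * np.sum(b2 * b2, axis=1)
        floor2 = 1e-4 * np.sum(b3 * b3, axis=1) * np.sum(b2 * b2, axis=1)
        n1sq = np.maximum(np.sum(n1 * n1, axis=1), floor1)
        n2sq = np.maximum(np.sum(n2 * n2, axis=1), floor2)
        # dphi/dx for the outer atoms (standard torsion gradient)
        gi = -(nb2 / n1sq)[:, None] * n1
        gl = (nb2 / n2sq)[:, None] * n2
        tp = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
        tq = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
        gj = -gi - tp * gi + tq * gl
        gk = -gl + tp * gi - tq * gl
        np.add.at(f, i, -dU[:, None] * gi)
        np.add.at(f, j, -dU[:, None] * gj)
        np.add.at(f, k, -dU[:, None] * gk)
        np.add.at(f, l, -dU[:, None] * gl)
        return energy

    def _nonbonded(self, x, f, brute_force: bool):
        if brute_force:
            n = len(x)
            ii, jj = np.triu_indices(n, k=1)
            codes = ii.astype(np.int64) * n + jj
            keep = ~np.isin(codes, self._excl_codes)
            pairs = np.column_stack([ii[keep], jj[keep]])
            sig = 0.5 * (self.sigma[pairs[:, 0]] + self.sigma[pairs[:, 1]])
            qq = self.charge[pairs[:, 0]] * self.charge[pairs[:, 1]]
        else:
            self._ensure_pairs(x)
            pairs, sig, qq = self._pairs, self._pair_sigma, self._pair_qq
        if pairs is None or not len(pairs):
            return 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        d = x[i] - x[j]
        r = np.linalg.norm(d, axis=1)
        energy = 0.0
        dUdr = np.zeros_like(r)

        wca_mask = r < _WCA_CUT * sig
        if np.any(wca_mask):
            rw = r[wca_mask]
            sw = sig[wca_mask]
            sr6 = (sw / rw) ** 6
            energy += float(np.sum(4.0 * self.eps_wca * (sr6**2 - sr6) + self.eps_wca))
            dUdr[wca_mask] += 4.0 * self.eps_wca * (-12.0 * sr6**2 + 6.0 * sr6) / rw

        dh_mask = (qq != 0.0) & (r < self.dh_cut)
        if np.any(dh_mask):
            rd = r[dh_mask]
            u = self.dh_prefactor * qq[dh_mask] / rd * np.exp(-rd / self.l_D_A)
            shift = self.dh_prefactor * qq[dh_mask] / self.dh_cut \
                * math.exp(-self.dh_cut / self.l_D_A)
            energy += float(np.sum(u - shift))
            dUdr[dh_mask] += -u * (1.0 / rd + 1.0 / self.l_D_A)

        coef = (-dUdr / r)[:, None] * d
        np.add.at(f, i, coef)
        np.add.at(f, j, -coef)
        return energy


def total_energy_forces(structure: CGStructure, params: ForceFieldParameters,
                        T: float = 300.0, I: float = 150.0):
    """One-shot total energy (kcal/mol) and per-bead forces (kcal/mol/A).

    Forces are the exact negative gradient of the returned energy; nonbonded
    pairs sharing any bonded term are excluded.
    """
    if structure.coords is None:
        raise ValueError("structure has no coordinates")
    model = EnergyModel(structure, params, T=T, I=I)
    return model.compute(structure.coords)
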