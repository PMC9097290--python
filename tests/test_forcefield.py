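"""Potentials, screening lengths and force-gradient consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duplexcg import energy, fixtures
from duplexcg.constants import CONSTANTS
from duplexcg.forcefield import (
    BondedTerm,
    bond_energy,
    angle_energy,
    dihedral_energy,
    debye_huckel_energy,
    debye_length,
    wca_energy,
    wrap_angle,
)

BOND = BondedTerm("bond", "5'-SP-3'", "AC", 6.0, 3.8)
ANGLE = BondedTerm("angle", "5'-SPS-3'", "AC", 12.0, 1.7)
DIHEDRAL = BondedTerm("dihedral", "5'-SPSP-3'", "AC", 1.5, 0.4)


class TestBondedPotentials:
    def test_bond_minimum_and_symmetry(self):
        assert bond_energy(BOND.equilibrium, BOND) == 0.0
        d = 0.1
        assert bond_energy(BOND.equilibrium + d, BOND) == pytest.approx(
            bond_energy(BOND.equilibrium - d, BOND))

    def test_bond_curvature_matches_stiffness(self):
        # U = k dr^2 has second derivative 2k
        h = 1e-4
        r0 = BOND.equilibrium
        second = (bond_energy(r0 + h, BOND) - 2 * bond_energy(r0, BOND)
                  + bond_energy(r0 - h, BOND)) / h**2
        assert second == pytest.approx(2.0 * BOND.stiffness, rel=1e-6)

    def test_bond_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            bond_energy(0.0, BOND)

    def test_angle_minimum_symmetry_and_domain(self):
        assert angle_energy(ANGLE.equilibrium, ANGLE) == 0.0
        assert angle_energy(ANGLE.equilibrium + 0.2, ANGLE) == pytest.approx(
            angle_energy(ANGLE.equilibrium - 0.2, ANGLE))
        with pytest.raises(ValueError):
            angle_energy(3.5, ANGLE)

    def test_angle_variance_from_boltzmann_sampling(self):
        # direct Monte-Carlo of exp(-U/kBT): var = kBT/(2k)
        rng = np.random.default_rng(7)
        kBT = CONSTANTS.kB_kcal_mol * 300.0
        proposals = rng.uniform(0.5, 2.9, 400_000)
        weights = np.exp(-angle_energy(proposals, ANGLE) / kBT)
        keep = rng.uniform(0, 1, len(proposals)) < weights
        var = np.var(proposals[keep])
        assert var == pytest.approx(kBT / (2 * ANGLE.stiffness), rel=0.02)

    def test_dihedral_minimum_at_phi0_plus_pi(self):
        phi_min = DIHEDRAL.equilibrium + math.pi
        grid = np.arange(-math.pi, math.pi, 1e-4)
        vals = dihedral_energy(grid, DIHEDRAL)
        assert abs(wrap_angle(grid[np.argmin(vals)] - phi_min)) < 1e-3
        assert dihedral_energy(phi_min, DIHEDRAL) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-10, 10))
    @settings(deadline=None, max_examples=50)
    def test_dihedral_periodicity(self, phi):
        assert dihedral_energy(phi, DIHEDRAL) == pytest.approx(
            dihedral_energy(phi + 2 * math.pi, DIHEDRAL), abs=1e-10)


class TestNonbonded:
    def test_wca_cutoff_value_and_monotonicity(self):
        sigma = 4.0
        cutoff = 2 ** (1 / 6) * sigma
        assert wca_energy(cutoff, sigma) == 0.0
        assert wca_energy(cutoff + 1.0, sigma) == 0.0
        assert wca_energy(sigma, sigma, eps=1.0) == pytest.approx(1.0)
        r = np.linspace(0.8 * sigma, cutoff, 2000)
        u = wca_energy(r, sigma)
        assert np.all(np.diff(u) <= 1e-12)

    def test_wca_continuous_at_cutoff(self):
        sigma = 4.0
        cutoff = 2 ** (1 / 6) * sigma
        assert wca_energy(cutoff - 1e-8, sigma) == pytest.approx(0.0, abs=1e-6)

    def test_debye_length_values(self):
        # hand evaluation with the model's constants
        assert debye_length(300.0, 150.0) == pytest.approx(0.788, abs=0.005)
        assert debye_length(300.0, 1000.0) == pytest.approx(0.305, abs=0.005)

    @given(st.floats(100, 500), st.floats(1, 2000))
    @settings(deadline=None, max_examples=50)
    def test_debye_length_scaling(self, T, I):
        # l_D ~ sqrt(T/I) exactly
        assert debye_length(T, 4 * I) == pytest.approx(debye_length(T, I) / 2, rel=1e-12)
        assert debye_length(4 * T, I) == pytest.approx(debye_length(T, I) * 2, rel=1e-12)

    def test_debye_huckel_limits(self):
        assert debye_huckel_energy(8.0, 0.0, -0.6, 0.79) == 0.0
        # unscreened limit reproduces the bare Coulomb energy
        r = 10.0
        coulomb = CONSTANTS.coulomb_kcal_A * 0.36 / (CONSTANTS.epsr * r)
        assert debye_huckel_energy(r, -0.6, -0.6, 1e9) == pytest.approx(
            coulomb, rel=1e-6)

    def test_debye_huckel_screening_bound(self):
        l_D = 0.79
        r = 7.0
        u1 = debye_huckel_energy(r, -0.6, -0.6, l_D)
        u2 = debye_huckel_energy(2 * r, -0.6, -0.6, l_D)
        assert u2 / u1 < math.exp(-r / (10 * l_D)) / 2


class TestForcesAreNegativeGradients:
    def test_full_molecule_finite_differences(self, toy_ff):
        helix = fixtures.ideal_helix_coords("ACGTA")
        model = energy.EnergyModel(helix, toy_ff)
        rng = np.random.default_rng(0)
        x = helix.coords + rng.normal(0, 0.15, helix.coords.shape)
        e0, forces = model.compute(x, brute_force_pairs=True)
        h = 1e-5
        num = np.zeros_like(forces)
        for i in range(x.shape[0]):
            for d in range(3):
                xp = x.copy(); xp[i, d] += h
                xm = x.copy(); xm[i, d] -= h
                num[i, d] = -(model.compute(xp, brute_force_pairs=True)[0]
                              - model.compute(xm, brute_force_pairs=True)[0]) / (2 * h)
        scale = np.abs(forces).max()
        assert np.abs(forces - num).max() / scale < 1e-5

    def test_neighbor_list_matches_brute_force(self, toy_ff):
        helix = fixtures.ideal_helix_coords("ACGTACGT")
        model = energy.EnergyModel(helix, toy_ff)
        rng = np.random.default_rng(1)
        x = helix.coords + rng.normal(0, 0.2, helix.coords.shape)
        e1, f1 = model.compute(x)
        e2, f2 = model.compute(x, brute_force_pairs=True)
        assert e1 == pytest.approx(e2, abs=1e-10)
        assert np.abs(f1 - f2).max() < 1e-10

    def test_two_bead_bond_at_equilibrium_has_zero_force(self, toy_ff):
        helix = fixtures.ideal_helix_coords("AT")
        model = energy.EnergyModel(helix, toy_ff)
        # bonded terms at their measured equilibria: only the weak screened
        # electrostatics contributes, and it acts on phosphates only
        _, forces = model.compute(helix.coords)
        sugar = helix.bead_id("S", 1, 1)
        base = helix.bead_id("B", 1, 1)
        assert np.abs(forces[[sugar, base]]).max() < 1e-9


class TestParameterTables:
    def test_missing_entry_is_named(self, toy_ff):
        from duplexcg.forcefield import MissingParameterError
        from duplexcg.topology import build_topology

        broken = dict(toy_ff.bonded)
        del broken[("bond", "5'-BB-3'", "AC")]
        ff2 = type(toy_ff)(bonded=broken, sigma=toy_ff.sigma)
        with pytest.raises(MissingParameterError, match="5'-BB-3'.*AC"):
            build_topology("TACT", ff2)

    def test_context_cardinality_validation(self, toy_ff):
        from duplexcg.forcefield import ForceFieldParameters

        entries = [t for t in toy_ff.bonded.values()
                   if not (t.class_label == "BB-WC" and t.context == "CG")]
        with pytest.raises(ValueError, match="BB-WC"):
            ForceFieldParameters.from_entries(
                entries, sigma=toy_ff.sigma, context_types=toy_ff.context_types)

    def test_save_load_round_trip(self, toy_ff, tmp_path):
        for name in ("ff.csv", "ff.json"):
            path = tmp_path / name
            toy_ff.save(path)
            back = type(toy_ff).load(path)
            assert back.n_entries() == toy_ff.n_entries()
            for key, term in toy_ff.bonded.items():
                assert back.bonded[key].stiffness == pytest.approx(term.stiffness)
                assert back.bonded[key].equilibrium == pytest.approx(term.equilibrium)
            assert back.q_phosphate == toy_ff.q_phosphate
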