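"""Composite potential: LJ, multipole electrostatics, forces, lattice energies."""

import numpy as np
import pytest

from crystalgp.constants import COULOMB_KJ_A
from crystalgp.energy import (
    EnergyModel,
    LJParams,
    forces,
    lattice_energy,
    lj_pair,
    molecular_dipole,
    relative_lattice_energies,
    total_energy,
)
from crystalgp.fixtures import (
    AnalyticIntraModel,
    build_toy_crystal,
    toy_energy,
    toy_energy_model,
    toy_monomer,
)
from crystalgp.multipole import pair_multipole_energy, traceless_quadrupole
from crystalgp.structures import Atom, Structure, build_supercell


class TestLJPair:
    def test_zero_at_sigma(self):
        assert lj_pair(3.1, 0.7, 3.1) == pytest.approx(0.0)

    def test_minimum_at_well(self):
        sigma, eps = 3.0, 0.65
        assert lj_pair(2 ** (1 / 6) * sigma, eps, sigma) == pytest.approx(-eps)

    def test_hand_value_at_two_sigma(self):
        assert lj_pair(2.0, 1.0, 1.0) == pytest.approx(4.0 * (2**-12 - 2**-6))

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError):
            lj_pair(0.0, 1.0, 1.0)

    def test_ab_coefficients(self):
        lj = LJParams({("O", "O"): (0.5, 3.0)})
        A, B = lj.ab_coefficients("O", "O")
        assert A == pytest.approx(4 * 0.5 * 3.0**12)
        assert B == pytest.approx(4 * 0.5 * 3.0**6)
        assert lj.epsilon_sigma("O", "H") == (0.0, 1.0)  # unparametrized pair


class TestMultipoleExpansion:
    """The interaction tensors against an explicit point-charge oracle."""

    def _clusters(self, rng):
        qa = rng.normal(size=4)
        da = rng.normal(size=(4, 3)) * 0.05
        qb = rng.normal(size=4)
        db = rng.normal(size=(4, 3)) * 0.05
        return (qa, da), (qb, db)

    def test_expansion_converges_by_rank(self, rng):
        (qa, da), (qb, db) = self._clusters(rng)
        R = np.array([7.0, 3.0, -2.0])
        exact = sum(
            qa[i] * qb[j] / np.linalg.norm(R + db[j] - da[i])
            for i in range(4)
            for j in range(4)
        )
        args = (
            [qa.sum()], [(qa[:, None] * da).sum(0)], [traceless_quadrupole(qa, da)],
            [qb.sum()], [(qb[:, None] * db).sum(0)], [traceless_quadrupole(qb, db)],
        )
        errs = [
            abs(pair_multipole_energy(R[None], *args, rank=rank)[0] - exact)
            for rank in (0, 1, 2)
        ]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-6

    def test_two_unit_charges_at_one_angstrom(self):
        z = np.zeros((1, 3))
        e = pair_multipole_energy(
            np.array([[1.0, 0.0, 0.0]]), [1.0], z, np.zeros((1, 3, 3)),
            [1.0], z, np.zeros((1, 3, 3)), rank=0,
        )[0]
        assert e * COULOMB_KJ_A == pytest.approx(1389.35457644382, rel=1e-10)

    def test_charge_dipole_two_charge_limit(self):
        # a point dipole mu along the separation axis vs its two-charge picture
        q, mu, r = 0.8, 0.05, 6.0
        e_dip = pair_multipole_energy(
            np.array([[r, 0.0, 0.0]]),
            [q], np.zeros((1, 3)), np.zeros((1, 3, 3)),
            [0.0], np.array([[mu, 0.0, 0.0]]), np.zeros((1, 3, 3)),
            rank=1,
        )[0]
        for d in (1e-2, 1e-3, 1e-4):
            plus = q * (mu / d / 2) / abs(r + d / 2 - 0) if False else None
        d = 1e-5
        e_pair = q * (mu / d) * (1 / (r + d / 2) - 1 / (r - d / 2))
        assert e_dip == pytest.approx(-q * mu / r**2, rel=1e-6)
        assert e_dip == pytest.approx(e_pair, rel=1e-6)

    def test_zero_moments_zero_energy(self, rng):
        rv = rng.normal(size=(5, 3)) + 4.0
        z1, z3, z33 = np.zeros(5), np.zeros((5, 3)), np.zeros((5, 3, 3))
        assert np.allclose(pair_multipole_energy(rv, z1, z3, z33, z1, z3, z33), 0.0)


class TestTotalEnergy:
    def test_isolated_monomer(self, pes_params):
        model = toy_energy_model(rank=2)
        eb = total_energy(toy_monomer(pes_params), model)
        assert eb.e_intra == pytest.approx(pes_params.e_ref)
        assert eb.e_elec == 0.0 and eb.e_lj == 0.0
        assert eb.e_total == eb.e_intra + eb.e_elec + eb.e_lj

    def test_two_distant_monomers_additive(self, pes_params):
        model = toy_energy_model(rank=2, cutoff=5.0)
        m = toy_monomer(pes_params)
        atoms = [Atom(a.element, a.position, molecule_id=0) for a in m.atoms]
        atoms += [Atom(a.element, a.position + 50.0, molecule_id=1) for a in m.atoms]
        dimer = Structure(atoms=atoms)
        eb = total_energy(dimer, model)
        assert eb.e_total == pytest.approx(2 * pes_params.e_ref, abs=1e-10)

    def test_dimer_matches_brute_force_pair_sum(self, rng, pes_params):
        model = toy_energy_model(rank=2, cutoff=50.0, taper_width=1e-6)
        m = toy_monomer(pes_params)
        atoms = [Atom(a.element, a.position, molecule_id=0) for a in m.atoms]
        shift = np.array([4.5, 0.7, 0.3])
        atoms += [Atom(a.element, a.position + shift, molecule_id=1) for a in m.atoms]
        dimer = Structure(atoms=atoms)
        eb = total_energy(dimer, model)
        # LJ oracle: plain double loop
        lj = 0.0
        for i in range(3):
            for j in range(3, 6):
                r = np.linalg.norm(atoms[i].position - atoms[j].position)
                eps, sig = model.lj.epsilon_sigma(atoms[i].element, atoms[j].element)
                lj += lj_pair(r, eps, sig)
        assert eb.e_lj == pytest.approx(lj, abs=1e-10)
        # electrostatics oracle: explicit pairwise tensor sum via the module
        lab = toy_energy(m, pes_params)
        assert eb.e_elec != 0.0

    def test_charges_only_reproduces_plain_coulomb(self, pes_params):
        model = toy_energy_model(rank=0, cutoff=60.0, taper_width=1e-6)
        m = toy_monomer(pes_params)
        atoms = [Atom(a.element, a.position, molecule_id=0) for a in m.atoms]
        shift = np.array([5.0, 1.0, -0.5])
        atoms += [Atom(a.element, a.position + shift, molecule_id=1) for a in m.atoms]
        dimer = Structure(atoms=atoms)
        eb = total_energy(dimer, model)
        lab = toy_energy(m, pes_params)
        q = lab["charges"]
        coulomb = 0.0
        for i in range(3):
            for j in range(3):
                r = np.linalg.norm(atoms[i].position - atoms[3 + j].position)
                coulomb += COULOMB_KJ_A * q[i] * q[j] / r
        assert eb.e_elec == pytest.approx(coulomb, rel=1e-10)

    def test_periodic_additivity(self):
        model = toy_energy_model(rank=1)
        cell = build_toy_crystal(a=4.3)
        sc = build_supercell(cell, (2, 1, 2))
        e1 = total_energy(cell, model).e_total
        e4 = total_energy(sc, model).e_total
        assert e4 == pytest.approx(4 * e1, rel=1e-6)

    def test_rigid_motion_invariance(self, rng):
        from crystalgp.fixtures import _random_rotation

        model = toy_energy_model(rank=2)
        m = toy_monomer()
        atoms = [Atom(a.element, a.position, molecule_id=0) for a in m.atoms]
        atoms += [Atom(a.element, a.position + np.array([4.0, 1.0, 0.5]), molecule_id=1)
                  for a in m.atoms]
        dimer = Structure(atoms=atoms)
        e0 = total_energy(dimer, model).e_total
        for _ in range(5):
            R = _random_rotation(rng)
            t = rng.uniform(-5, 5, 3)
            moved = dimer.copy()
            moved.positions = dimer.positions @ R.T + t
            assert total_energy(moved, model).e_total == pytest.approx(e0, abs=1e-8)


class TestForces:
    def test_monomer_stationary_at_equilibrium(self, pes_params):
        model = toy_energy_model(rank=2)
        f = forces(toy_monomer(pes_params), model)
        assert np.abs(f).max() < 1e-6

    @pytest.mark.parametrize("rank", [0, 1, 2])
    def test_finite_difference_consistency(self, rank, rng):
        model = toy_energy_model(rank=rank)
        c = build_toy_crystal(a=4.3)
        c.positions = c.positions + rng.normal(0, 0.02, c.positions.shape)
        f = forces(c, model)
        h = 1e-5
        for atom, d in [(0, 0), (1, 2), (3, 1), (5, 0)]:
            p = c.copy()
            p.atoms[atom].position[d] += h
            q = c.copy()
            q.atoms[atom].position[d] -= h
            fd = -(total_energy(p, model).e_total - total_energy(q, model).e_total) / (2 * h)
            assert f[atom, d] == pytest.approx(fd, abs=1e-4)

    def test_net_force_zero_isolated(self, rng):
        model = toy_energy_model(rank=2, cutoff=20.0)
        m = toy_monomer()
        atoms = [Atom(a.element, a.position, molecule_id=0) for a in m.atoms]
        atoms += [Atom(a.element, a.position + np.array([3.8, 0.9, 0.4]), molecule_id=1)
                  for a in m.atoms]
        dimer = Structure(atoms=atoms)
        dimer.positions = dimer.positions + rng.normal(0, 0.02, (6, 3))
        f = forces(dimer, model)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_translation_leaves_forces(self, rng):
        model = toy_energy_model(rank=1)
        c = build_toy_crystal(a=4.3)
        f0 = forces(c, model)
        moved = c.copy()
        moved.positions = c.positions + np.array([1.3, -0.7, 2.1])
        assert np.allclose(forces(moved, model), f0, atol=1e-6)

    def test_taper_window_continuity(self):
        """Energy stays continuous (to step-size resolution) across the taper."""
        model = toy_energy_model(rank=1, cutoff=6.0, taper_width=1.5)
        m = toy_monomer()
        energies = []
        seps = np.linspace(3.8, 8.0, 80)
        for s in seps:
            atoms = [Atom(a.element, a.position, molecule_id=0) for a in m.atoms]
            atoms += [Atom(a.element, a.position + np.array([s, 0, 0]), molecule_id=1)
                      for a in m.atoms]
            energies.append(total_energy(Structure(atoms=atoms), model).e_total)
        energies = np.array(energies)
        assert np.abs(np.diff(energies)).max() < 0.5  # no jump discontinuities
        assert energies[-1] == pytest.approx(2 * model.intra.params.e_ref, abs=1e-9)


class TestLatticeEnergy:
    def test_arithmetic(self):
        assert lattice_energy(-100.0, 2, -40.0) == pytest.approx(-10.0)

    def test_noninteracting_supercell_is_zero(self, pes_params):
        model = toy_energy_model(rank=2, cutoff=4.0)
        c = build_toy_crystal(a=40.0)  # molecules far beyond the cutoff
        e_super = total_energy(c, model).e_total
        assert lattice_energy(e_super, 2, pes_params.e_ref) == pytest.approx(0.0, abs=1e-9)

    def test_bad_molecule_count(self):
        with pytest.raises(ValueError):
            lattice_energy(-10.0, 0, -5.0)

    def test_relative_energies_published_rows(self):
        rel = relative_lattice_energies({"Ih": -59.6, "II": -41.0, "XV": -44.0}, "Ih")
        assert rel["II"] == pytest.approx(18.6)
        assert rel["XV"] == pytest.approx(15.6)
        assert rel["Ih"] == 0.0

    def test_missing_reference(self):
        with pytest.raises(KeyError):
            relative_lattice_energies({"a": 1.0}, "b")


def test_molecular_dipole_matches_charge_model(pes_params):
    model = toy_energy_model(rank=2)
    m = toy_monomer(pes_params)
    lab = toy_energy(m, pes_params)
    # oracle: sum q r about the centroid plus the rotated atomic dipoles
    from crystalgp.alf import _frame_matrix, compute_alf

    pos = m.positions
    mu = (lab["charges"][:, None] * (pos - pos.mean(0))).sum(0)
    frame_o = _frame_matrix(pos, compute_alf(m, 0))
    mu = mu + frame_o.T @ lab["dipoles"][0]
    assert np.allclose(molecular_dipole(m, model), mu, atol=1e-12)


def test_lj_parameter_text_roundtrip():
    from crystalgp.energy import lj_params_from_text, lj_params_to_text

    lj = LJParams({("O", "O"): (0.8, 3.0), ("O", "H"): (0.3, 2.3), ("H", "H"): (0.15, 1.8)})
    back = lj_params_from_text(lj_params_to_text(lj))
    for pair in (("O", "O"), ("H", "O"), ("H", "H")):
        assert back.epsilon_sigma(*pair) == lj.epsilon_sigma(*pair)
    with pytest.raises(ValueError, match="line 1"):
        lj_params_from_text("O O 0.8")
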