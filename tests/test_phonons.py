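"""Finite-displacement phonons against analytic spring-crystal oracles."""

import numpy as np
import pytest

from crystalgp.constants import CM1_TO_KJMOL, KB, SQRT_EV_TO_CM1
from crystalgp.model_potentials import (
    BornSpringModel,
    diatomic_chain,
    diatomic_chain_dispersion,
)
from crystalgp.phonons import (
    ImaginaryModeError,
    assemble_force_constants,
    density_of_states,
    band_structure,
    displaced_supercell,
    dynamical_matrix,
    finite_displacement_force_constants,
    free_energy_curve,
    generate_displacements,
    helmholtz_free_energy,
    mesh_frequencies,
    modes_at,
    phonon_frequencies,
)
from crystalgp.structures import Atom, Lattice, Structure, build_supercell


@pytest.fixture(scope="module")
def cubic_spring_cell():
    """Two-atom cubic cell with longitudinal+transverse springs (stable)."""
    cell = Structure(
        atoms=[
            Atom("O", [0.0, 0.0, 0.0], molecule_id=0),
            Atom("H", [1.5, 1.5, 1.5], mass=2.0, molecule_id=1),
        ],
        lattice=Lattice(np.eye(3) * 3.0),
        periodic=True,
    )
    model = BornSpringModel(cell, cutoff=2.8, k_l=150.0, k_t=30.0)
    return cell, model


def spring_fc(cell, model, expansion, **kwargs):
    """FD force constants with the spring calculator built on the supercell."""
    super_model = model.supercell_model(expansion)
    return finite_displacement_force_constants(cell, expansion, super_model.forces, **kwargs)


class TestDisplacements:
    @pytest.mark.parametrize("n_atoms,expected", [(36, 216), (2304, 13824), (1, 6)])
    def test_task_count_is_six_per_atom(self, n_atoms, expected):
        atoms = [Atom("H", [0.01 * k, 0.0, 0.0], molecule_id=k) for k in range(n_atoms)]
        s = Structure(atoms=atoms, lattice=Lattice(np.eye(3) * 100.0), periodic=True)
        assert len(generate_displacements(s)) == expected

    def test_each_task_moves_one_atom_by_amplitude(self, cubic_spring_cell):
        cell, _ = cubic_spring_cell
        tasks = generate_displacements(cell, amplitude=5e-3)
        ref = build_supercell(cell, (2, 2, 2))
        for task in tasks[:6]:
            sc = displaced_supercell(cell, (2, 2, 2), task)
            delta = sc.positions - ref.positions
            assert np.count_nonzero(np.abs(delta) > 1e-12) == 1
            assert abs(delta).max() == pytest.approx(5e-3)

    def test_bad_amplitude(self, cubic_spring_cell):
        cell, _ = cubic_spring_cell
        with pytest.raises(ValueError):
            generate_displacements(cell, amplitude=0.0)


class TestForceConstants:
    def test_matches_analytic_hessian(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2), acoustic_sum_rule=False)
        phi_exact, offsets = model.analytic_force_constants((2, 2, 2))
        scale = np.abs(phi_exact).max()
        assert np.abs(fc.phi - phi_exact).max() < 1e-6 * scale

    def test_acoustic_sum_rule_enforced(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        row = fc.phi.sum(axis=(2, 3))
        assert np.abs(row).max() < 1e-8

    def test_missing_task_reported(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        tasks = generate_displacements(cell)[:-1]
        sm = model.supercell_model((2, 2, 2))
        task_forces = [sm.forces(displaced_supercell(cell, (2, 2, 2), t)) for t in tasks]
        with pytest.raises(ValueError, match="missing"):
            assemble_force_constants(cell, (2, 2, 2), task_forces, tasks)

    def test_central_difference_order(self, cubic_spring_cell):
        """Halving the amplitude changes nothing measurably on a harmonic model."""
        cell, model = cubic_spring_cell
        fc1 = spring_fc(cell, model, (2, 2, 2), amplitude=5e-3)
        fc2 = spring_fc(cell, model, (2, 2, 2), amplitude=2.5e-3)
        assert np.abs(fc1.phi - fc2.phi).max() < 1e-6 * np.abs(fc1.phi).max()


class TestDynamicalMatrix:
    def test_gamma_acoustic_modes_vanish(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        freqs = modes_at(fc, (0.0, 0.0, 0.0)).frequencies
        assert np.abs(freqs[:3]).max() < 0.1  # cm^-1
        assert freqs[3] > 10.0

    def test_hermitian_at_random_q(self, cubic_spring_cell, rng):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        for _ in range(5):
            D = dynamical_matrix(fc, rng.uniform(-0.5, 0.5, 3))
            assert np.abs(D - D.conj().T).max() < 1e-10

    def test_eigenvectors_orthonormal(self, cubic_spring_cell, rng):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        modes = modes_at(fc, (0.25, 0.1, 0.0))
        W = modes.eigenvectors
        assert np.abs(W.conj().T @ W - np.eye(W.shape[1])).max() < 1e-8

    def test_diatomic_chain_closed_form(self):
        cell, spring = diatomic_chain(m1=1.0, m2=2.0, a=2.0, k=100.0)
        fc = spring_fc(cell, spring, (8, 1, 1))
        for qx in np.linspace(0.0, 0.5, 50):
            freqs = modes_at(fc, (qx, 0.0, 0.0)).frequencies
            ac, opt = diatomic_chain_dispersion(qx, m1=1.0, m2=2.0, k=100.0)
            got = np.sort(freqs)[-2:]  # the two longitudinal branches
            want = np.sort(SQRT_EV_TO_CM1 * np.sqrt([ac, opt]))
            if qx == 0.0:
                want[0] = 0.0
                got = np.array([0.0, got[1]])
            assert np.allclose(got, want, rtol=1e-8, atol=1e-6)

    def test_negative_eigenvalue_reported_negative(self):
        D = np.diag([-4.0, 9.0, 16.0]).astype(complex)
        modes = phonon_frequencies(D)
        assert (modes.frequencies < 0).sum() == 1
        assert modes.frequencies[0] == pytest.approx(-2.0 * SQRT_EV_TO_CM1)

    def test_isotropic_matrix_frequencies(self):
        D = (5.0 * np.eye(3)).astype(complex)
        modes = phonon_frequencies(D)
        assert np.allclose(modes.frequencies, np.sqrt(5.0) * SQRT_EV_TO_CM1)


class TestBandsAndDos:
    def test_trivial_gamma_path_constant(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        _, modes, _ = band_structure(fc, [("G", (0, 0, 0)), ("G", (0, 0, 0))], 5)
        ref = modes[0].frequencies
        for m in modes:
            assert np.allclose(m.frequencies, ref, atol=1e-8)

    def test_endpoints_match_direct_evaluation(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        _, modes, _ = band_structure(fc, [("G", (0, 0, 0)), ("X", (0.5, 0, 0))], 10)
        direct = modes_at(fc, (0.5, 0.0, 0.0)).frequencies
        assert np.allclose(modes[-1].frequencies, direct, atol=1e-10)

    def test_dos_integral_counts_modes(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        dos = density_of_states(fc, mesh=(6, 6, 6), broadening=8.0)
        integral = np.trapezoid(dos.density, dos.frequencies)
        assert integral == pytest.approx(6.0, rel=0.01)  # 3 N_b = 6

    def test_dos_mesh_refinement_stable(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        d1 = density_of_states(fc, mesh=(4, 4, 4), broadening=10.0)
        d2 = density_of_states(fc, mesh=(8, 8, 8), broadening=10.0)
        i1 = np.trapezoid(d1.density, d1.frequencies)
        i2 = np.trapezoid(d2.density, d2.frequencies)
        assert i1 == pytest.approx(i2, rel=1e-3)

    def test_single_mode_dos_peak(self):
        # 1-atom cell with an on-site-like spring crystal: flat optical modes
        cell = Structure(
            atoms=[Atom("O", [0.0, 0.0, 0.0])],
            lattice=Lattice(np.eye(3) * 3.0),
            periodic=True,
        )
        model = BornSpringModel(cell, cutoff=3.5, k_l=100.0, k_t=100.0)
        fc = spring_fc(cell, model, (2, 2, 2))
        dos = density_of_states(fc, mesh=(4, 4, 4), broadening=5.0)
        assert np.trapezoid(dos.density, dos.frequencies) == pytest.approx(3.0, rel=0.01)


class TestHelmholtz:
    def test_zero_temperature_is_zero_point_energy(self):
        f, u, s = helmholtz_free_energy([100.0], 0.0)
        assert f == pytest.approx(0.5 * 100.0 * CM1_TO_KJMOL)
        assert u == f and s == 0.0

    def test_single_mode_extended_precision_value(self):
        """nu = 100 cm^-1 at 300 K against an mpmath-style high-precision oracle.

        Evaluated with Fraction-free closed form: F = e/2 + kB T ln(1 - exp(-e/kBT)).
        """
        from decimal import Decimal, getcontext

        getcontext().prec = 50
        e = Decimal(100) * Decimal(repr(CM1_TO_KJMOL))
        kbt = Decimal(repr(KB)) * Decimal(300)
        x = e / kbt
        # exp/ln at 50 digits
        ex = (-x).exp()
        f_exact = e / 2 + kbt * (1 - ex).ln()
        f, u, s = helmholtz_free_energy([100.0], 300.0)
        assert f == pytest.approx(float(f_exact), rel=1e-10)
        assert f == pytest.approx(u - 300.0 * s, rel=1e-12)

    @pytest.mark.parametrize("T", [10.0, 50.0, 150.0, 300.0])
    def test_bridge_relation_consistency(self, T, rng):
        nus = rng.uniform(20.0, 3000.0, size=12)
        f, u, s = helmholtz_free_energy(nus, T)
        assert f == pytest.approx(u - T * s, abs=1e-10)
        assert s >= 0.0

    def test_classical_limit(self):
        # kB T >> h c nu: F per mode -> kB T ln(h c nu / kB T)
        nu = 0.02  # cm^-1, so that the ratio exceeds 100 at 10 K
        T = 10.0
        x = nu * CM1_TO_KJMOL / (KB * T)
        assert 1.0 / x > 100
        f, _, _ = helmholtz_free_energy([nu], T)
        classical = KB * T * np.log(nu * CM1_TO_KJMOL / (KB * T))
        assert f == pytest.approx(classical, rel=0.01)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ImaginaryModeError):
            helmholtz_free_energy([-5.0, 100.0], 100.0)

    def test_curve_concave_and_entropy_increasing(self, cubic_spring_cell):
        cell, model = cubic_spring_cell
        fc = spring_fc(cell, model, (2, 2, 2))
        T = np.linspace(10, 300, 30)
        out = free_energy_curve(fc, T, mesh=(3, 3, 3))
        d2F = np.diff(out["F"], 2)
        assert np.all(d2F <= 1e-10)
        assert np.all(np.diff(out["S"]) >= -1e-12)

    def test_supercell_doubling_leaves_gamma_frequencies(self, cubic_spring_cell):
        """Extracting the unit cell from a larger supercell changes nothing for
        short-ranged interactions: Gamma frequencies agree within 0.5 cm^-1."""
        cell, model = cubic_spring_cell
        fc2 = spring_fc(cell, model, (2, 2, 2))
        fc3 = spring_fc(cell, model, (3, 3, 3))
        g2 = modes_at(fc2, (0.0, 0.0, 0.0)).frequencies
        g3 = modes_at(fc3, (0.0, 0.0, 0.0)).frequencies
        assert np.abs(g2 - g3).max() < 0.5


def test_mesh_weights_sum_to_one(cubic_spring_cell):
    cell, model = cubic_spring_cell
    fc = spring_fc(cell, model, (2, 2, 2))
    freqs, weights, is_gamma = mesh_frequencies(fc, (3, 3, 3))
    assert weights.sum() == pytest.approx(1.0)
    assert is_gamma.sum() == 1
    assert freqs.shape == (27, 6)
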