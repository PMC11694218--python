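"""Analytic model potentials with known Hessians.

These are first-class test instruments: a Born spring crystal whose force
constants are available in closed form (the oracle for the finite-displacement
phonon pipeline), and a double-well extension used to engineer a dynamical
instability with a known distorted minimum.  Both expose the same
``energy(structure)`` / ``forces(structure)`` calculator surface as the
machine-learned model, so they drop into the relaxation, phonon and
mode-mapping code unchanged.
"""

from __future__ import annotations

import numpy as np

from .structures import Atom, Lattice, Structure, build_supercell

__all__ = ["BornSpringModel", "DoubleWellModel", "diatomic_chain", "diatomic_chain_dispersion"]


class BornSpringModel:
    """Harmonic springs between reference-structure neighbours.

    Each pair within ``cutoff`` of the reference geometry (periodic images
    included) is coupled by the 3x3 force-constant block
    K = k_l u u^T + k_t (I - u u^T) with u the reference bond direction:
    ``k_l`` resists bond stretching, ``k_t`` shearing.  The energy is
    (1/2) sum_pairs (du_i - du_j)^T K (du_i - du_j) in the displacements from
    the reference, so the Hessian is exactly the assembled K blocks.
    """

    def __init__(self, reference: Structure, cutoff: float, k_l: float, k_t: float = 0.0):
        self.reference = reference.copy()
        self.cutoff = float(cutoff)
        self.k_l = float(k_l)
        self.k_t = float(k_t)
        self.pairs = self._build_pairs()

    def _build_pairs(self):
        ref = self.reference
        pos = ref.positions
        n = len(ref)
        pairs = []
        if ref.periodic:
            cell = ref.lattice.cell
            recip = np.linalg.inv(cell)
            heights = 1.0 / np.linalg.norm(recip, axis=0)
            nmax = np.ceil(self.cutoff / heights + 1).astype(int)
            shift_ints = [
                (a, b, c)
                for a in range(-nmax[0], nmax[0] + 1)
                for b in range(-nmax[1], nmax[1] + 1)
                for c in range(-nmax[2], nmax[2] + 1)
                if (a, b, c) >= (0, 0, 0)
            ]
        else:
            shift_ints = [(0, 0, 0)]
            cell = np.zeros((3, 3))
        for nvec in shift_ints:
            shift = np.asarray(nvec, dtype=float) @ cell
            for i in range(n):
                j_start = i + 1 if nvec == (0, 0, 0) else 0
                for j in range(j_start, n):
                    if nvec == (0, 0, 0) and i == j:
                        continue
                    d = pos[j] + shift - pos[i]
                    r = np.linalg.norm(d)
                    if 1e-9 < r < self.cutoff:
                        u = d / r
                        K = self.k_l * np.outer(u, u) + self.k_t * (np.eye(3) - np.outer(u, u))
                        pairs.append((i, j, np.array(nvec), K))
        return pairs

    def _displacements(self, structure: Structure):
        return structure.positions - self.reference.positions

    def energy(self, structure: Structure) -> float:
        u = self._displacements(structure)
        e = 0.0
        for i, j, _, K in self.pairs:
            du = u[i] - u[j]
            e += 0.5 * du @ K @ du
        return float(e)

    def forces(self, structure: Structure) -> np.ndarray:
        u = self._displacements(structure)
        f = np.zeros_like(u)
        for i, j, _, K in self.pairs:
            g = K @ (u[i] - u[j])
            f[i] -= g
            f[j] += g
        return f

    def supercell_model(self, expansion):
        """The same spring model defined on the expanded reference cell.

        Finite-displacement phonon runs evaluate forces on supercells; this is
        the calculator to hand them.
        """
        return BornSpringModel(
            build_supercell(self.reference, expansion), self.cutoff, self.k_l, self.k_t
        )

    def analytic_force_constants(self, expansion):
        """Exact Phi[(0 k a), (l' k' b)] folded onto the given supercell.

        Returns ``(phi, cell_offsets)`` with phi of shape
        (n_b, 3, n_cells, n_b, 3) and offsets enumerated in the same order the
        supercell builder uses.  Springs whose cell offset folds onto the same
        supercell site accumulate, which is exactly what a finite-displacement
        run on that supercell measures.
        """
        n1, n2, n3 = expansion
        n_b = len(self.reference)
        offsets = [(i, j, k) for i in range(n1) for j in range(n2) for k in range(n3)]
        index = {o: m for m, o in enumerate(offsets)}
        phi = np.zeros((n_b, 3, len(offsets), n_b, 3))
        for i, j, nvec, K in self.pairs:
            images = [(i, j, tuple(nvec)), (j, i, tuple(-nvec))]
            for k, kp, off in images:
                fold = (off[0] % n1, off[1] % n2, off[2] % n3)
                m = index[fold]
                phi[k, :, m, kp, :] += -K
                phi[k, :, index[(0, 0, 0)], k, :] += K
        return phi, np.array(offsets)


class DoubleWellModel:
    """Spring crystal plus a quartic double well along one displacement pattern.

    E = E_spring + a s^4 - b s^2 with s = sum_i p_i . (r_i - r_i^ref) and the
    pattern p chosen (ideally) as an eigenvector of the spring Hessian.  The
    reference structure is then a saddle point; the two minima sit at
    s* = +-sqrt((2b - lambda_p) / 4a) where lambda_p is the spring curvature
    along p, and both minima are dynamically stable for b > 0.
    """

    def __init__(self, spring: BornSpringModel, pattern: np.ndarray, a: float, b: float):
        self.spring = spring
        pattern = np.asarray(pattern, dtype=float).reshape(len(spring.reference), 3)
        self.pattern = pattern / np.linalg.norm(pattern)
        self.a = float(a)
        self.b = float(b)

    def _s(self, structure: Structure):
        du = structure.positions - self.spring.reference.positions
        return float(np.sum(self.pattern * du))

    def energy(self, structure: Structure) -> float:
        s = self._s(structure)
        return self.spring.energy(structure) + self.a * s**4 - self.b * s**2

    def forces(self, structure: Structure) -> np.ndarray:
        s = self._s(structure)
        return self.spring.forces(structure) + (2.0 * self.b * s - 4.0 * self.a * s**3) * self.pattern


def diatomic_chain(m1=1.0, m2=2.0, a=2.0, k=100.0):
    """Two-atom linear chain along x embedded in 3-D, with spring constant k.

    The cell is padded in y and z so only nearest-neighbour x springs exist.
    Returns ``(cell_structure, spring_model)``; masses in amu, k in kJ/mol/Å².
    """
    lattice = Lattice(np.diag([a, 10.0 * a, 10.0 * a]))
    atoms = [
        Atom("H", [0.0, 0.0, 0.0], mass=m1, molecule_id=0),
        Atom("H", [a / 2.0, 0.0, 0.0], mass=m2, molecule_id=1),
    ]
    cell = Structure(atoms=atoms, lattice=lattice, periodic=True)
    spring = BornSpringModel(cell, cutoff=0.6 * a, k_l=k, k_t=0.0)
    return cell, spring


def diatomic_chain_dispersion(q_frac, m1=1.0, m2=2.0, k=100.0):
    """Closed-form optical/acoustic eigenvalues (kJ/mol/Å²/amu) at fractional q.

    omega^2 = k (1/m1 + 1/m2) +- k sqrt((1/m1 + 1/m2)^2 - 4 sin^2(q a/2)/(m1 m2))
    with q a = 2 pi q_frac.  Returns (acoustic, optical) as omega^2 values.
    """
    s2 = np.sin(np.pi * np.asarray(q_frac)) ** 2
    inv = 1.0 / m1 + 1.0 / m2
    root = np.sqrt(inv**2 - 4.0 * s2 / (m1 * m2))
    return k * (inv - root), k * (inv + root)

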