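"""Geometry and lattice data model.

``Structure`` is the universal geometry carrier of the package: an ordered set of
atoms with Cartesian positions (Å), optionally equipped with a periodic lattice
whose rows are the lattice vectors.  Coordinates stay Cartesian internally;
fractional coordinates appear only at I/O boundaries and when wrapping is
explicitly requested, so that finite-difference displacements remain continuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Lattice",
    "Structure",
    "DegenerateLatticeError",
    "ATOMIC_MASSES",
    "ATOMIC_NUMBERS",
    "cell_volume",
    "build_supercell",
    "percent_difference",
    "detect_molecules",
    "bonded_pairs",
]


class DegenerateLatticeError(ValueError):
    """Raised for lattices with non-positive or non-finite volume."""


ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20,
}

ATOMIC_MASSES = {  # amu, IUPAC 2021 conventional values
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
}

# covalent radii (Å, Cordero et al.) used by the bond-distance heuristic
COVALENT_RADII = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76,
}


@dataclass
class Atom:
    """One atom: chemical symbol, mass (amu), Cartesian position (Å), molecule tag."""

    element: str
    position: np.ndarray
    mass: float | None = None
    molecule_id: int = 0

    def __post_init__(self):
        if self.element not in ATOMIC_NUMBERS:
            raise ValueError(f"unknown element symbol {self.element!r}")
        if self.mass is None:
            self.mass = ATOMIC_MASSES[self.element]
        if self.mass <= 0:
            raise ValueError(f"non-positive mass {self.mass} for {self.element}")
        self.position = np.asarray(self.position, dtype=float).reshape(3)


class Lattice:
    """Periodic cell; rows of ``cell`` are the lattice vectors a, b, c in Å.

    When built from parameters, the standard crystallographic construction is
    used: a along x, b in the xy-plane.
    """

    def __init__(self, cell):
        cell = np.asarray(cell, dtype=float)
        if cell.shape != (3, 3):
            raise ValueError("cell must be a 3x3 matrix")
        det = float(np.linalg.det(cell))
        if not math.isfinite(det) or abs(det) < 1e-12:
            raise DegenerateLatticeError(f"degenerate cell, |det| = {abs(det):g}")
        self.cell = cell

    @classmethod
    def from_parameters(cls, a, b, c, alpha, beta, gamma):
        """Build from lengths (Å) and angles (degrees)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
        sg = math.sin(math.radians(gamma))
        if abs(sg) < 1e-12:
            raise DegenerateLatticeError("gamma is 0 or 180 degrees")
        cx = c * cb
        cy = c * (ca - cb * cg) / sg
        cz_sq = c * c - cx * cx - cy * cy
        if cz_sq <= 0:
            raise DegenerateLatticeError("angle combination closes the cell")
        return cls(
            [[a, 0.0, 0.0], [b * cg, b * sg, 0.0], [cx, cy, math.sqrt(cz_sq)]]
        )

    @property
    def parameters(self):
        """(a, b, c, alpha, beta, gamma) with lengths in Å, angles in degrees."""
        a, b, c = (float(np.linalg.norm(v)) for v in self.cell)

        def ang(u, v):
            return math.degrees(
                math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
            )

        return (
            a, b, c,
            ang(self.cell[1], self.cell[2]),
            ang(self.cell[0], self.cell[2]),
            ang(self.cell[0], self.cell[1]),
        )

    @property
    def volume(self):
        return abs(float(np.linalg.det(self.cell)))

    @property
    def reciprocal(self):
        """Rows are reciprocal lattice vectors (without the 2*pi factor)."""
        return np.linalg.inv(self.cell).T

    def cartesian(self, frac):
        return np.asarray(frac, dtype=float) @ self.cell

    def fractional(self, cart):
        return np.asarray(cart, dtype=float) @ np.linalg.inv(self.cell)

    def __eq__(self, other):
        return isinstance(other, Lattice) and np.allclose(self.cell, other.cell, atol=1e-12)


def cell_volume(lattice: Lattice) -> float:
    """Triclinic cell volume abc*sqrt(1 - cos²a - cos²b - cos²g + 2 cos a cos b cos g), Å³.

    Equals |det(cell)|; evaluated from the parameters so that volumes quoted from
    published (a, b, c, alpha, beta, gamma) rows are reproduced digit for digit.
    """
    a, b, c, alpha, beta, gamma = lattice.parameters
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0 or not math.isfinite(arg):
        raise DegenerateLatticeError("non-positive volume")
    return a * b * c * math.sqrt(arg)


@dataclass
class Structure:
    """Ordered atoms, optionally periodic.  ``meta`` carries provenance notes
    (e.g. how molecule ids were assigned)."""

    atoms: list
    lattice: Lattice | None = None
    periodic: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError("structure needs at least one atom")
        if self.periodic and self.lattice is None:
            raise ValueError("periodic structure requires a lattice")

    def __len__(self):
        return len(self.atoms)

    @property
    def positions(self):
        return np.array([a.position for a in self.atoms])

    @positions.setter
    def positions(self, value):
        value = np.asarray(value, dtype=float).reshape(len(self.atoms), 3)
        for atom, p in zip(self.atoms, value):
            atom.position = p.copy()

    @property
    def masses(self):
        return np.array([a.mass for a in self.atoms])

    @property
    def elements(self):
        return [a.element for a in self.atoms]

    @property
    def molecule_ids(self):
        return np.array([a.molecule_id for a in self.atoms])

    def fractional_positions(self):
        if self.lattice is None:
            raise ValueError("no lattice")
        return self.lattice.fractional(self.positions)

    def set_fractional_positions(self, frac):
        self.positions = self.lattice.cartesian(frac)

    def wrap(self):
        """Explicitly wrap fractional coordinates into [0, 1)."""
        self.set_fractional_positions(self.fractional_positions() % 1.0)
        return self

    def copy(self):
        return Structure(
            atoms=[Atom(a.element, a.position.copy(), a.mass, a.molecule_id) for a in self.atoms],
            lattice=Lattice(self.lattice.cell.copy()) if self.lattice is not None else None,
            periodic=self.periodic,
            meta=dict(self.meta),
        )

    def molecules(self):
        """Mapping molecule_id -> list of atom indices, in first-seen order."""
        groups: dict[int, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            groups.setdefault(atom.molecule_id, []).append(i)
        return groups


def percent_difference(value: float, reference: float) -> float:
    """100 (value - reference) / reference; the deviation-from-reference gauge."""
    if reference == 0:
        raise ValueError("zero reference")
    return 100.0 * (value - reference) / reference


def build_supercell(structure: Structure, expansion) -> Structure:
    """Replicate a periodic cell by positive integer factors (n1, n2, n3).

    Image molecules receive fresh, unique molecule ids so intermolecular terms
    see every image as its own molecule.
    """
    if not structure.periodic:
        raise ValueError("supercell requires a periodic structure")
    n1, n2, n3 = (int(n) for n in expansion)
    if min(n1, n2, n3) < 1:
        raise ValueError(f"expansion factors must be positive, got {expansion}")
    cell = structure.lattice.cell
    base_ids = sorted(structure.molecules())
    id_index = {m: k for k, m in enumerate(base_ids)}
    n_mols = len(base_ids)
    atoms = []
    image = 0
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                shift = i * cell[0] + j * cell[1] + k * cell[2]
                for atom in structure.atoms:
                    atoms.append(
                        Atom(
                            atom.element,
                            atom.position + shift,
                            atom.mass,
                            image * n_mols + id_index[atom.molecule_id],
                        )
                    )
                image += 1
    new_cell = cell * np.array([[n1], [n2], [n3]], dtype=float)
    return Structure(atoms=atoms, lattice=Lattice(new_cell), periodic=True, meta=dict(structure.meta))


def _pair_cutoff(el_i, el_j, scale=1.25):
    return scale * (COVALENT_RADII[el_i] + COVALENT_RADII[el_j])


def bonded_pairs(structure: Structure, bonds=None, scale=1.25):
    """Connectivity as a set of index pairs.

    Explicit ``bonds`` (iterable of (i, j)) win; otherwise a covalent-radius
    distance heuristic is applied (O-H bonds at the default scale fall under
    the 1.2 Å rule of thumb).
    """
    if bonds is not None:
        return {tuple(sorted(p)) for p in bonds}
    pos = structure.positions
    els = structure.elements
    out = set()
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if np.linalg.norm(pos[i] - pos[j]) < _pair_cutoff(els[i], els[j], scale):
                out.add((i, j))
    return out


def detect_molecules(structure: Structure, scale=1.25):
    """Assign molecule ids from connected components of the bond graph (in place).

    Records ``meta['molecule_id_source'] = 'distance-heuristic'``; structures
    with author-provided tags carry ``'explicit'`` instead.
    """
    n = len(structure)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in bonded_pairs(structure, scale=scale):
        parent[find(i)] = find(j)
    roots = {}
    for i, atom in enumerate(structure.atoms):
        r = find(i)
        atom.molecule_id = roots.setdefault(r, len(roots))
    structure.meta["molecule_id_source"] = "distance-heuristic"
    return structure
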