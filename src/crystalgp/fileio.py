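"""Structure I/O: extended XYZ and a P1 CIF dialect.

Extended XYZ layout::

    <natoms>
    Lattice="ax ay az bx by bz cx cy cz" Properties=species:S:1:pos:R:3:molecule_id:I:1
    O 0.0 0.0 0.0 0
    ...

The ``Lattice`` and ``molecule_id`` fields are optional; positions are
Cartesian Å.  The CIF dialect is P1 only (explicit fractional coordinates, no
symmetry operators) and is parsed/emitted with :mod:`gemmi.cif`.
"""

from __future__ import annotations

import re
import shlex

import numpy as np
from gemmi import cif as gemmi_cif

from .structures import Atom, ATOMIC_NUMBERS, Lattice, Structure, detect_molecules

__all__ = ["read_structure", "write_structure", "ParseError"]


class ParseError(ValueError):
    """Malformed structure file; message carries the offending line number."""


def read_structure(path, format=None) -> Structure:
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return _read_xyz(path)
    return _read_cif(path)


def write_structure(structure: Structure, path, format=None):
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(structure, path)
    else:
        _write_cif(structure, path)


def _infer_format(path, format):
    if format is not None:
        if format not in ("xyz", "cif"):
            raise ValueError(f"unsupported format {format!r}")
        return format
    name = str(path).lower()
    if name.endswith(".cif"):
        return "cif"
    if name.endswith(".xyz"):
        return "xyz"
    raise ValueError(f"cannot infer format of {path!r}; pass format='xyz' or 'cif'")


# --- extended XYZ ---

def _read_xyz(path) -> Structure:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: line 1: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: expected atom count") from None
    if len(lines) < natoms + 2:
        raise ParseError(
            f"{path}: line {len(lines)}: {natoms} atoms declared but "
            f"only {max(len(lines) - 2, 0)} atom records present"
        )
    comment = lines[1] if len(lines) > 1 else ""
    lattice = None
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) != 9:
            raise ParseError(f"{path}: line 2: Lattice field needs 9 numbers")
        lattice = Lattice(np.array(vals).reshape(3, 3))
    atoms = []
    have_mol = True
    for ln in range(2, 2 + natoms):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {ln + 1}: expected 'element x y z [molecule_id]'")
        el = parts[0]
        if el not in ATOMIC_NUMBERS:
            raise ParseError(f"{path}: line {ln + 1}: unknown element {el!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {ln + 1}: non-numeric coordinate") from None
        mol = 0
        if len(parts) >= 5:
            mol = int(parts[4])
        else:
            have_mol = False
        atoms.append(Atom(el, xyz, molecule_id=mol))
    s = Structure(atoms=atoms, lattice=lattice, periodic=lattice is not None)
    if have_mol:
        s.meta["molecule_id_source"] = "explicit"
    elif len(atoms) > 1:
        detect_molecules(s)
    return s


def _write_xyz(structure: Structure, path):
    comment_parts = []
    if structure.lattice is not None:
        cell = " ".join(f"{x:.12g}" for x in structure.lattice.cell.ravel())
        comment_parts.append(f'Lattice="{cell}"')
    comment_parts.append("Properties=species:S:1:pos:R:3:molecule_id:I:1")
    with open(path, "w") as fh:
        fh.write(f"{len(structure)}\n")
        fh.write(" ".join(comment_parts) + "\n")
        for a in structure.atoms:
            x, y, z = a.position
            fh.write(f"{a.element} {x:.12f} {y:.12f} {z:.12f} {a.molecule_id}\n")


# --- CIF-lite (P1) ---

def _read_cif(path) -> Structure:
    try:
        doc = gemmi_cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    block = doc.sole_block()

    def cell_item(tag):
        val = block.find_value(tag)
        if val is None:
            raise ParseError(f"{path}: missing {tag}")
        return float(gemmi_cif.as_number(val))

    lattice = Lattice.from_parameters(
        cell_item("_cell_length_a"), cell_item("_cell_length_b"), cell_item("_cell_length_c"),
        cell_item("_cell_angle_alpha"), cell_item("_cell_angle_beta"), cell_item("_cell_angle_gamma"),
    )
    table = block.find(
        "_atom_site_", ["type_symbol", "fract_x", "fract_y", "fract_z"]
    )
    if len(table) == 0:
        raise ParseError(f"{path}: no _atom_site_ loop")
    atoms = []
    for row in table:
        el = row[0]
        if el not in ATOMIC_NUMBERS:
            raise ParseError(f"{path}: unknown element {el!r} in _atom_site_ loop")
        frac = [gemmi_cif.as_number(row[k]) for k in (1, 2, 3)]
        atoms.append(Atom(el, lattice.cartesian(frac)))
    s = Structure(atoms=atoms, lattice=lattice, periodic=True)
    if len(atoms) > 1:
        detect_molecules(s)
    return s


def _write_cif(structure: Structure, path):
    if structure.lattice is None:
        raise ValueError("CIF output requires a lattice")
    a, b, c, al, be, ga = structure.lattice.parameters
    frac = structure.fractional_positions()
    lines = [
        "data_crystalgp",
        "_symmetry_space_group_name_H-M 'P 1'",
        "_symmetry_Int_Tables_number 1",
        f"_cell_length_a {a:.10f}",
        f"_cell_length_b {b:.10f}",
        f"_cell_length_c {c:.10f}",
        f"_cell_angle_alpha {al:.10f}",
        f"_cell_angle_beta {be:.10f}",
        f"_cell_angle_gamma {ga:.10f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, (atom, f) in enumerate(zip(structure.atoms, frac)):
        lines.append(
            f"{atom.element}{i + 1} {atom.element} {f[0]:.10f} {f[1]:.10f} {f[2]:.10f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
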