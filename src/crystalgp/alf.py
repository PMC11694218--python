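"""Atomic local frames (ALF) and rotation/translation-invariant features.

Every atom being modelled is the origin of its own right-handed frame: the x
axis points at the highest-priority bonded atom (A_x), the xy-plane is fixed by
the next reference atom (A_xy), and z completes the right-handed system.  The
feature vector of an N-atom molecule has length 3N-6: the two ALF distances and
the enclosed angle, followed by (r, theta, phi) spherical coordinates of every
remaining atom in the local frame.  phi is the cyclic feature, kept in
(-pi, pi].

Priority rule: (atomic number, atomic mass, original index), descending — a
deterministic stand-in for Cahn-Ingold-Prelog ordering that coincides with it
for the small molecules this package targets.  The ordering of the non-ALF tail
is ascending original atom index; both conventions are recorded in model
metadata by the training layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import ATOMIC_NUMBERS, Structure, bonded_pairs

__all__ = [
    "ALFDefinition",
    "DegenerateFrameError",
    "compute_alf",
    "featurize",
    "feature_length",
    "cyclic_mask",
]


class DegenerateFrameError(ValueError):
    """ALF atoms are collinear; the frame is under-determined."""


@dataclass(frozen=True)
class ALFDefinition:
    center: int
    x_axis_atom: int
    plane_atom: int

    def __post_init__(self):
        if len({self.center, self.x_axis_atom, self.plane_atom}) != 3:
            raise ValueError("ALF needs three distinct atom indices")


def feature_length(n_atoms: int) -> int:
    return 3 * n_atoms - 6


def _priority_key(structure: Structure, idx: int):
    a = structure.atoms[idx]
    # descending (Z, mass), ascending original index as the final tie-break
    return (-ATOMIC_NUMBERS[a.element], -a.mass, idx)


def compute_alf(structure: Structure, center: int, connectivity=None) -> ALFDefinition:
    """Choose the two ALF reference atoms for ``center``.

    For a centre with two or more bonded neighbours, A_x and A_xy are the two
    highest-priority neighbours.  For a terminal centre, A_x is its single
    neighbour and A_xy the highest-priority atom bonded to A_x (other than the
    centre itself).
    """
    if len(structure) < 3:
        raise ValueError("ALF requires at least 3 atoms")
    pairs = bonded_pairs(structure, bonds=connectivity)
    neighbours = {}
    for i, j in pairs:
        neighbours.setdefault(i, []).append(j)
        neighbours.setdefault(j, []).append(i)
    bonded = sorted(neighbours.get(center, []), key=lambda k: _priority_key(structure, k))
    if not bonded:
        raise ValueError(f"atom {center} has no bonded neighbours")
    if len(bonded) >= 2:
        return ALFDefinition(center, bonded[0], bonded[1])
    ax = bonded[0]
    candidates = sorted(
        (k for k in neighbours.get(ax, []) if k != center),
        key=lambda k: _priority_key(structure, k),
    )
    if not candidates:
        raise ValueError(f"terminal atom {center}: x-axis atom {ax} has no other neighbour")
    return ALFDefinition(center, ax, candidates[0])


def _cross(a, b):
    return np.array([
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    ])


def _frame_matrix(positions, alf: ALFDefinition):
    """Rows are the unit vectors (x, y, z) of the local frame."""
    c = positions[alf.center]
    v1 = positions[alf.x_axis_atom] - c
    v2 = positions[alf.plane_atom] - c
    r1 = math.sqrt(v1 @ v1)
    r2 = math.sqrt(v2 @ v2)
    if r1 < 1e-12 or r2 < 1e-12:
        raise DegenerateFrameError("coincident ALF atoms")
    xhat = v1 / r1
    normal = _cross(xhat, v2)
    nn = math.sqrt(normal @ normal)
    if nn / r2 < 1e-6:
        raise DegenerateFrameError(
            f"ALF atoms {alf.center}, {alf.x_axis_atom}, {alf.plane_atom} are collinear"
        )
    zhat = normal / nn
    yhat = _cross(zhat, xhat)
    return np.array([xhat, yhat, zhat])


def featurize(structure: Structure, center: int, alf: ALFDefinition) -> np.ndarray:
    """Feature vector of length 3N-6 for the molecule containing ``center``.

    Features: [r(C->A_x), r(C->A_xy), angle(A_x, C, A_xy)] then, for each
    non-ALF atom in ascending index order, (r, theta, phi) in the local frame:
    theta is the polar angle from the x-axis (the A_x bond direction) and phi
    the azimuth around it, atan2(z, y) in (-pi, pi] — zero in the ALF plane,
    sign carrying the out-of-plane handedness (a mirror image flips phi only).
    """
    positions = structure.positions
    frame = _frame_matrix(positions, alf)
    c = positions[alf.center]
    v1 = positions[alf.x_axis_atom] - c
    v2 = positions[alf.plane_atom] - c
    r1 = math.sqrt(v1 @ v1)
    r2 = math.sqrt(v2 @ v2)
    angle = math.acos(min(1.0, max(-1.0, float(v1 @ v2) / (r1 * r2))))
    feats = [r1, r2, angle]
    used = {alf.center, alf.x_axis_atom, alf.plane_atom}
    for k in range(len(structure)):
        if k in used:
            continue
        local = frame @ (positions[k] - c)
        r = math.sqrt(local @ local)
        if r < 1e-12:
            raise DegenerateFrameError(f"atom {k} coincides with the frame origin")
        theta = math.acos(min(1.0, max(-1.0, local[0] / r)))
        phi = math.atan2(local[2], local[1])
        if phi <= -math.pi:  # atan2 returns (-pi, pi]; normalize the -pi edge
            phi = math.pi
        feats.extend([r, theta, phi])
    return np.array(feats)


def cyclic_mask(n_features: int) -> np.ndarray:
    """Boolean mask of every third feature (0-based indices 2, 5, 8, ...).

    These are the angular features: the ALF enclosed angle and the azimuths phi
    of the tail atoms.  The kernel wraps differences of these features into
    (-pi, pi]; for the enclosed angle (range (0, pi)) wrapping never fires, so
    marking it cyclic is exact and keeps the mask a uniform stride.
    """
    mask = np.zeros(n_features, dtype=bool)
    mask[2::3] = True
    return mask
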