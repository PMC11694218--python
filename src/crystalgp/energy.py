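"""Composite potential energy surface for molecular crystals.

Total energy splits as E = E_intra + E_elec + E_LJ:

* ``E_intra`` — sum of machine-learned (or analytic) per-atom energies,
  evaluated molecule by molecule from ALF features; intramolecular LJ and
  electrostatics are excluded entirely, this term owns everything inside a
  molecule.
* ``E_elec`` — point-multipole electrostatics (charge through quadrupole,
  configurable rank) between atoms of different molecules, with moments
  predicted in each atom's local frame and rotated into the global frame at
  every evaluation.  The real-space sum runs over molecule pairs (periodic
  images included): a pair enters when the molecule centres are within the
  cutoff and its whole atom-atom block is tapered smoothly to zero there.
  Cutting on neutral molecular units rather than atoms keeps the truncated
  tail dipolar and free of ionic shell artifacts.
* ``E_LJ`` — 12-6 Lennard-Jones between atoms of different molecules, summed
  over periodic images with an atom-pair taper at its own cutoff.

Forces: analytic for LJ and for the intramolecular term (kernel gradient
chained through feature Jacobians); electrostatic pair forces by central
differences on the pair vector (antisymmetric by construction, so Newton's
third law holds exactly), plus a finite-difference term for the geometry
dependence of the predicted moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gpr
from .alf import compute_alf, featurize
from .constants import COULOMB_KJ_A
from .multipole import pair_multipole_energy
from .structures import Structure

__all__ = [
    "LJParams",
    "MultipoleSet",
    "EnergyBreakdown",
    "EnergyModel",
    "GPRIntraModel",
    "lj_pair",
    "total_energy",
    "forces",
    "lattice_energy",
    "relative_lattice_energies",
    "lj_params_from_text",
    "lj_params_to_text",
]


class LJParams:
    """Symmetric per-element-pair table of (epsilon kJ/mol, sigma Å)."""

    def __init__(self, pairs):
        self._table = {}
        for (ei, ej), (eps, sigma) in dict(pairs).items():
            if eps < 0 or sigma <= 0:
                raise ValueError(f"bad LJ parameters for ({ei}, {ej}): {(eps, sigma)}")
            self._table[frozenset((ei, ej))] = (float(eps), float(sigma))

    def epsilon_sigma(self, el_i, el_j):
        key = frozenset((el_i, el_j))
        if key not in self._table:
            return (0.0, 1.0)  # unparametrized pairs do not interact
        return self._table[key]

    def ab_coefficients(self, el_i, el_j):
        """A = 4 eps sigma^12, B = 4 eps sigma^6."""
        eps, sigma = self.epsilon_sigma(el_i, el_j)
        return 4.0 * eps * sigma**12, 4.0 * eps * sigma**6


def lj_pair(r, epsilon, sigma):
    """12-6 potential 4 eps [(sigma/r)^12 - (sigma/r)^6], kJ/mol."""
    if np.any(np.asarray(r) <= 0):
        raise ValueError("non-positive separation")
    sr6 = (sigma / np.asarray(r, dtype=float)) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


@dataclass
class MultipoleSet:
    """Per-atom moments: charge (e), dipole (e Å), traceless quadrupole (e Å^2)."""

    charges: np.ndarray
    dipoles: np.ndarray
    quadrupoles: np.ndarray
    rank: int = 2

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.charges)
        self.dipoles = np.asarray(self.dipoles, dtype=float).reshape(n, 3)
        self.quadrupoles = np.asarray(self.quadrupoles, dtype=float).reshape(n, 3, 3)
        tr = np.abs(np.trace(self.quadrupoles, axis1=1, axis2=2))
        if np.any(tr > 1e-10):
            raise ValueError(f"quadrupoles not traceless (max |trace| {tr.max():g})")


@dataclass
class EnergyBreakdown:
    e_intra: float
    e_elec: float
    e_lj: float

    @property
    def e_total(self):
        return self.e_intra + self.e_elec + self.e_lj


class GPRIntraModel:
    """Per-atom GPR models of one molecular species.

    ``energy_models`` is a list (one entry per atom of the molecule, in atom
    order) of trained :class:`~crystalgp.gpr.GPRModel` for the atomic energy.
    ``charge_models`` / ``dipole_models`` / ``quadrupole_models`` follow the
    same layout; dipoles carry 3 models per atom (local-frame components) and
    quadrupoles 5 (independent components of a traceless symmetric tensor, in
    the order xx, yy, xy, xz, yz).  Missing moment models default to zero
    moments.
    """

    def __init__(self, energy_models, charge_models=None, dipole_models=None,
                 quadrupole_models=None):
        self.energy_models = list(energy_models)
        self.charge_models = charge_models
        self.dipole_models = dipole_models
        self.quadrupole_models = quadrupole_models

    @property
    def n_atoms(self):
        return len(self.energy_models)

    def atomic_energies(self, features):
        return np.array(
            [gpr.predict(m, f) for m, f in zip(self.energy_models, features)]
        )

    def atomic_energy_feature_grads(self, features):
        return [gpr.predict_gradient(m, f) for m, f in zip(self.energy_models, features)]

    def atomic_multipoles_local(self, features):
        n = self.n_atoms
        charges = np.zeros(n)
        dipoles = np.zeros((n, 3))
        quads = np.zeros((n, 3, 3))
        if self.charge_models is not None:
            charges = np.array(
                [gpr.predict(m, f) for m, f in zip(self.charge_models, features)]
            )
        if self.dipole_models is not None:
            for a, (models, f) in enumerate(zip(self.dipole_models, features)):
                dipoles[a] = [gpr.predict(m, f) for m in models]
        if self.quadrupole_models is not None:
            for a, (models, f) in enumerate(zip(self.quadrupole_models, features)):
                xx, yy, xy, xz, yz = (gpr.predict(m, f) for m in models)
                quads[a] = [[xx, xy, xz], [xy, yy, yz], [xz, yz, -xx - yy]]
        return charges, dipoles, quads


@dataclass
class EnergyModel:
    """Composite potential: intra model + LJ table + multipole electrostatics.

    ``elec_cutoff`` and ``vdw_cutoff`` in Å (12 Å production default), ``rank``
    is the highest multipole rank entering the electrostatics (2 =
    quadrupole), ``taper_width`` the switching window over which pair terms
    are taken smoothly to zero at the cutoff.  ``neutralize`` removes the
    (small) net charge a regression model leaves on each molecule by an equal
    per-atom shift, keeping periodic sums absolutely convergent.
    """

    intra: object
    lj: LJParams
    elec_cutoff: float = 12.0
    vdw_cutoff: float = 12.0
    rank: int = 2
    taper_width: float = 2.0
    neutralize: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.rank <= 2:
            raise ValueError("electrostatic rank must be 0, 1 or 2")


def _taper(r, cutoff, width):
    """Quintic smoothstep: 1 below cutoff-width, 0 above cutoff, C^2 across."""
    t = np.clip((np.asarray(r, dtype=float) - (cutoff - width)) / width, 0.0, 1.0)
    return 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t * t)


def _taper_derivative(r, cutoff, width):
    t = np.clip((np.asarray(r, dtype=float) - (cutoff - width)) / width, 0.0, 1.0)
    return -(30.0 * t**2 - 60.0 * t**3 + 30.0 * t**4) / width


# --- molecule featurization ---

class _MoleculeContext:
    """ALFs, features, frame matrices and feature Jacobians of one molecule."""

    def __init__(self, structure: Structure, indices, alfs):
        self.indices = list(indices)
        sub_atoms = [structure.atoms[i] for i in self.indices]
        self.sub = Structure(
            atoms=[a for a in sub_atoms], lattice=None, periodic=False
        )
        self.alfs = alfs
        self.features = [featurize(self.sub, a.center, a) for a in alfs]

    def frames(self):
        from .alf import _frame_matrix

        pos = self.sub.positions
        return [_frame_matrix(pos, a) for a in self.alfs]


def _molecule_alfs(structure: Structure, indices):
    if len(indices) < 3:
        # mono/diatomic species carry no local frame; their moments (if any)
        # are treated as already global and their intra energy as frame-free
        return []
    sub = Structure(atoms=[structure.atoms[i] for i in indices])
    return [compute_alf(sub, k) for k in range(len(indices))]


def _rotate_moments(charges, dipoles_local, quads_local, frames):
    """ALF-frame moments -> global frame (frame rows are the local axes).

    Without frames (molecules too small to define one) the local moments are
    passed through unrotated.
    """
    n = len(charges)
    if not frames:
        return np.array(dipoles_local, dtype=float), np.array(quads_local, dtype=float)
    dipoles = np.zeros((n, 3))
    quads = np.zeros((n, 3, 3))
    for a, R in enumerate(frames):
        dipoles[a] = R.T @ dipoles_local[a]
        quads[a] = R.T @ quads_local[a] @ R
    return dipoles, quads


def _evaluate_molecules(structure: Structure, model: EnergyModel):
    """Per-molecule contexts plus global-frame moments for every atom."""
    groups = structure.molecules()
    n = len(structure)
    charges = np.zeros(n)
    dipoles = np.zeros((n, 3))
    quads = np.zeros((n, 3, 3))
    contexts = []
    alf_cache: dict[tuple, list] = {}
    for mol_id in sorted(groups):
        idx = groups[mol_id]
        key = tuple(structure.atoms[i].element for i in idx)
        if key not in alf_cache:
            alf_cache[key] = _molecule_alfs(structure, idx)
        ctx = _MoleculeContext(structure, idx, alf_cache[key])
        q, d_loc, th_loc = model.intra.atomic_multipoles_local(ctx.features)
        if model.neutralize:
            q = q - q.sum() / len(q)
        d_glob, th_glob = _rotate_moments(q, d_loc, th_loc, ctx.frames())
        charges[idx] = q
        dipoles[idx] = d_glob
        quads[idx] = th_glob
        contexts.append(ctx)
    return contexts, MultipoleSet(charges, dipoles, quads, model.rank)


# --- pair list over periodic images ---

def _image_shifts(lattice, cutoff):
    """Integer translations whose shift can bring atoms within the cutoff."""
    cell = lattice.cell
    recip = np.linalg.inv(cell)
    heights = 1.0 / np.linalg.norm(recip, axis=0)  # plane spacings
    nmax = np.ceil(cutoff / heights + 1).astype(int)
    shifts = []
    for n1 in range(-nmax[0], nmax[0] + 1):
        for n2 in range(-nmax[1], nmax[1] + 1):
            for n3 in range(-nmax[2], nmax[2] + 1):
                shifts.append((n1, n2, n3))
    return np.array(shifts) @ cell, np.array(shifts)


def _pair_list(structure: Structure, cutoff):
    """Intermolecular pairs (i, j, rvec) within the cutoff, each counted once.

    For the zero translation, i < j; non-zero translations are restricted to a
    lexicographically positive half-space so that (i, j, n) and (j, i, -n)
    never both appear.  Pairs within the same molecule (zero translation only)
    are excluded.
    """
    pos = structure.positions
    mol = structure.molecule_ids
    n = len(pos)
    out_i, out_j, out_r = [], [], []

    diff0 = pos[None, :, :] - pos[:, None, :]
    if structure.periodic:
        shifts, ints = _image_shifts(structure.lattice, cutoff)
    else:
        shifts, ints = np.zeros((1, 3)), np.zeros((1, 3), dtype=int)
    for shift, nvec in zip(shifts, ints):
        nt = tuple(nvec)
        if nt < (0, 0, 0):
            continue  # half-space
        rvec = diff0 + shift
        dist = np.linalg.norm(rvec, axis=-1)
        if nt == (0, 0, 0):
            mask = np.triu(np.ones((n, n), dtype=bool), 1)
            mask &= mol[:, None] != mol[None, :]
        else:
            mask = np.ones((n, n), dtype=bool)
        mask &= dist < cutoff
        ii, jj = np.nonzero(mask)
        out_i.append(ii)
        out_j.append(jj)
        out_r.append(rvec[ii, jj])
    return (
        np.concatenate(out_i),
        np.concatenate(out_j),
        np.concatenate(out_r) if out_r else np.zeros((0, 3)),
    )


def _lj_energy(structure, model, i, j, rvec):
    r = np.linalg.norm(rvec, axis=1)
    sel = r < model.vdw_cutoff
    if not np.any(sel):
        return 0.0
    els = structure.elements
    eps = np.empty(sel.sum())
    sig = np.empty(sel.sum())
    for k, (a, b) in enumerate(zip(i[sel], j[sel])):
        eps[k], sig[k] = model.lj.epsilon_sigma(els[a], els[b])
    return float(np.sum(lj_pair(r[sel], eps, sig) * _taper(r[sel], model.vdw_cutoff, model.taper_width)))


class _ElecPairs:
    """Concatenated atom-pair arrays of all molecule-image pairs in the cutoff.

    The taper weight of a pair is a function of the two molecule centres, not
    of the individual atom separation, so whole (neutral) molecules enter and
    leave the interaction sphere together.
    """

    def __init__(self, structure: Structure, cutoff: float, taper_width: float):
        pos = structure.positions
        groups = structure.molecules()
        self.mol_ids = sorted(groups)
        self.mol_atoms = {m: np.array(groups[m]) for m in self.mol_ids}
        centers = {m: pos[idx].mean(axis=0) for m, idx in self.mol_atoms.items()}
        radius = max(
            float(np.max(np.linalg.norm(pos[idx] - centers[m], axis=1)))
            for m, idx in self.mol_atoms.items()
        )
        if structure.periodic:
            shifts, ints = _image_shifts(structure.lattice, cutoff + 2 * radius)
        else:
            shifts, ints = np.zeros((1, 3)), np.zeros((1, 3), dtype=int)
        I, J, RV, BID = [], [], [], []
        self.blocks = []  # (mol_a, mol_b, s_taper, ds_taper, u_com, n_a, n_b)
        for shift, nvec in zip(shifts, ints):
            nt = tuple(nvec)
            if nt < (0, 0, 0):
                continue
            for a_pos, ma in enumerate(self.mol_ids):
                for mb in self.mol_ids[a_pos + (1 if nt == (0, 0, 0) else 0):] \
                        if nt == (0, 0, 0) else self.mol_ids:
                    d = centers[mb] + shift - centers[ma]
                    rcom = float(np.linalg.norm(d))
                    if rcom >= cutoff or rcom < 1e-9:
                        continue
                    ia, ib = self.mol_atoms[ma], self.mol_atoms[mb]
                    ii = np.repeat(ia, len(ib))
                    jj = np.tile(ib, len(ia))
                    I.append(ii)
                    J.append(jj)
                    RV.append(pos[jj] + shift - pos[ii])
                    BID.append(np.full(len(ii), len(self.blocks)))
                    self.blocks.append((
                        ma, mb,
                        float(_taper(rcom, cutoff, taper_width)),
                        float(_taper_derivative(rcom, cutoff, taper_width)),
                        d / rcom, len(ia), len(ib),
                    ))
        if I:
            self.i = np.concatenate(I)
            self.j = np.concatenate(J)
            self.rvec = np.concatenate(RV)
            self.block_id = np.concatenate(BID)
        else:
            self.i = np.zeros(0, dtype=int)
            self.j = np.zeros(0, dtype=int)
            self.rvec = np.zeros((0, 3))
            self.block_id = np.zeros(0, dtype=int)
        self.s = np.array([b[2] for b in self.blocks]) if self.blocks else np.zeros(0)

    def pair_energies(self, moments, rank, rvec=None, charges=None, dipoles=None,
                      quadrupoles=None, subset=None):
        """Raw (untapered) pair energies in e^2/Å; arrays may be overridden."""
        idx = slice(None) if subset is None else subset
        i, j = self.i[idx], self.j[idx]
        rv = self.rvec[idx] if rvec is None else rvec
        q = moments.charges if charges is None else charges
        d = moments.dipoles if dipoles is None else dipoles
        t = moments.quadrupoles if quadrupoles is None else quadrupoles
        return pair_multipole_energy(rv, q[i], d[i], t[i], q[j], d[j], t[j], rank=rank)

    def energy(self, moments, rank):
        if len(self.i) == 0:
            return 0.0
        e = self.pair_energies(moments, rank)
        return COULOMB_KJ_A * float(np.sum(e * self.s[self.block_id]))


def total_energy(structure: Structure, model: EnergyModel) -> EnergyBreakdown:
    """Energy breakdown of a gas-phase or periodic structure, kJ/mol."""
    contexts, moments = _evaluate_molecules(structure, model)
    e_intra = float(
        sum(np.sum(model.intra.atomic_energies(ctx.features)) for ctx in contexts)
    )
    if structure.periodic and abs(moments.charges.sum()) > 1e-8:
        raise ValueError(
            f"net cell charge {moments.charges.sum():g} e; periodic electrostatics "
            "is conditionally convergent for charged cells"
        )
    i, j, rvec = _pair_list(structure, model.vdw_cutoff)
    e_lj = _lj_energy(structure, model, i, j, rvec) if len(i) else 0.0
    elec = _ElecPairs(structure, model.elec_cutoff, model.taper_width)
    e_elec = elec.energy(moments, model.rank)
    return EnergyBreakdown(e_intra, e_elec, e_lj)


# --- forces ---

def _intra_feature_jacobian(ctx: _MoleculeContext):
    """d features / d molecule coordinates, (n_feat, n_atoms*3).

    The (r1, r2, angle) core uses the analytic gradients; spherical-tail
    features (molecules beyond 3 atoms) fall back to central differences.
    """
    pos = ctx.sub.positions
    n = len(ctx.indices)
    jacs = []
    for alf, feats in zip(ctx.alfs, ctx.features):
        J = np.zeros((len(feats), 3 * n))
        c, ax, axy = alf.center, alf.x_axis_atom, alf.plane_atom
        v1 = pos[ax] - pos[c]
        v2 = pos[axy] - pos[c]
        r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
        u1, u2 = v1 / r1, v2 / r2
        J[0, 3 * ax:3 * ax + 3] = u1
        J[0, 3 * c:3 * c + 3] = -u1
        J[1, 3 * axy:3 * axy + 3] = u2
        J[1, 3 * c:3 * c + 3] = -u2
        cos_t = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
        sin_t = float(np.sqrt(max(1.0 - cos_t**2, 1e-24)))
        g_ax = (cos_t * u1 - u2) / (r1 * sin_t)
        g_axy = (cos_t * u2 - u1) / (r2 * sin_t)
        J[2, 3 * ax:3 * ax + 3] = g_ax
        J[2, 3 * axy:3 * axy + 3] = g_axy
        J[2, 3 * c:3 * c + 3] = -(g_ax + g_axy)
        if len(feats) > 3:
            h = 1e-6
            for coord in range(3 * n):
                atom, d = divmod(coord, 3)
                orig = ctx.sub.atoms[atom].position[d]
                ctx.sub.atoms[atom].position[d] = orig + h
                fp = featurize(ctx.sub, c, alf)
                ctx.sub.atoms[atom].position[d] = orig - h
                fm = featurize(ctx.sub, c, alf)
                ctx.sub.atoms[atom].position[d] = orig
                J[3:, coord] = (fp[3:] - fm[3:]) / (2.0 * h)
        jacs.append(J)
    return jacs


def forces(structure: Structure, model: EnergyModel) -> np.ndarray:
    """Per-atom forces -dE/dr, kJ/mol/Å."""
    n = len(structure)
    f = np.zeros((n, 3))
    contexts, moments = _evaluate_molecules(structure, model)
    els = structure.elements

    # intramolecular: analytic kernel gradient through the feature Jacobian
    for ctx in contexts:
        if not ctx.alfs:
            continue  # frame-free species: intra energy has no feature gradient
        grads = model.intra.atomic_energy_feature_grads(ctx.features)
        jacs = _intra_feature_jacobian(ctx)
        g_mol = np.zeros(3 * len(ctx.indices))
        for de_df, J in zip(grads, jacs):
            g_mol += de_df @ J
        for a, idx in enumerate(ctx.indices):
            f[idx] -= g_mol[3 * a:3 * a + 3]

    # LJ: analytic pair forces with atom-pair taper
    i, j, rvec = _pair_list(structure, model.vdw_cutoff)
    if len(i):
        r = np.linalg.norm(rvec, axis=1)
        sel = r < model.vdw_cutoff
        if np.any(sel):
            eps = np.empty(sel.sum())
            sig = np.empty(sel.sum())
            for k, (a, b) in enumerate(zip(i[sel], j[sel])):
                eps[k], sig[k] = model.lj.epsilon_sigma(els[a], els[b])
            rs = r[sel]
            sr6 = (sig / rs) ** 6
            dv = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / rs
            v = 4.0 * eps * (sr6 * sr6 - sr6)
            s = _taper(rs, model.vdw_cutoff, model.taper_width)
            ds = _taper_derivative(rs, model.vdw_cutoff, model.taper_width)
            dedr = dv * s + v * ds  # scalar dE/d|r|
            pair_f = (dedr / rs)[:, None] * rvec[sel]  # dE/drvec
            np.subtract.at(f, j[sel], pair_f)
            np.add.at(f, i[sel], pair_f)

    elec = _ElecPairs(structure, model.elec_cutoff, model.taper_width)
    if len(elec.i):
        s_pair = elec.s[elec.block_id]
        # (1) pair-vector derivative at fixed moments and taper
        h = 1e-5
        for d in range(3):
            step = np.zeros(3)
            step[d] = h
            ep = elec.pair_energies(moments, model.rank, rvec=elec.rvec + step)
            em = elec.pair_energies(moments, model.rank, rvec=elec.rvec - step)
            dedr_d = COULOMB_KJ_A * s_pair * (ep - em) / (2.0 * h)
            np.subtract.at(f[:, d], elec.j, dedr_d)
            np.add.at(f[:, d], elec.i, dedr_d)

        # (2) taper derivative through the molecule centres
        e_raw = COULOMB_KJ_A * elec.pair_energies(moments, model.rank)
        e_block = np.zeros(len(elec.blocks))
        np.add.at(e_block, elec.block_id, e_raw)
        for (ma, mb, _s, ds, u_com, n_a, n_b), e_b in zip(elec.blocks, e_block):
            g = ds * e_b  # dE/dR_com
            f[elec.mol_atoms[ma]] += (g / n_a) * u_com
            f[elec.mol_atoms[mb]] -= (g / n_b) * u_com

        # (3) geometry dependence of the predicted moments (finite differences)
        f += _moment_coupling_forces(structure, model, contexts, moments, elec)
    return f


def _molecule_moments_at(ctx, model, positions):
    """Global-frame moments of one molecule at overridden positions."""
    from .alf import _frame_matrix

    saved = [a.position.copy() for a in ctx.sub.atoms]
    for a, p in zip(ctx.sub.atoms, positions):
        a.position = np.asarray(p, dtype=float)
    feats = [featurize(ctx.sub, alf.center, alf) for alf in ctx.alfs]
    q, d_loc, th_loc = model.intra.atomic_multipoles_local(feats)
    if model.neutralize:
        q = q - q.sum() / len(q)
    frames = [_frame_matrix(ctx.sub.positions, alf) for alf in ctx.alfs]
    d_glob, th_glob = _rotate_moments(q, d_loc, th_loc, frames)
    for a, p in zip(ctx.sub.atoms, saved):
        a.position = p
    return q, d_glob, th_glob


def _moment_coupling_forces(structure, model, contexts, moments, elec: _ElecPairs):
    """-d E_elec / d x through the moments' dependence on molecular geometry.

    E_elec is bilinear in the site moments, so the per-atom duals dE/dM are
    assembled analytically in one pass over the pair list; only the moment
    prediction itself is differentiated by central differences of the
    molecule's coordinates.
    """
    from .multipole import pair_moment_gradients

    n = len(structure)
    out = np.zeros((n, 3))
    w = COULOMB_KJ_A * elec.s[elec.block_id]
    g = pair_moment_gradients(
        elec.rvec,
        moments.charges[elec.i], moments.dipoles[elec.i], moments.quadrupoles[elec.i],
        moments.charges[elec.j], moments.dipoles[elec.j], moments.quadrupoles[elec.j],
        rank=model.rank,
    )
    dq = np.zeros(n)
    dmu = np.zeros((n, 3))
    dth = np.zeros((n, 3, 3))
    np.add.at(dq, elec.i, w * g["qa"])
    np.add.at(dq, elec.j, w * g["qb"])
    np.add.at(dmu, elec.i, w[:, None] * g["mua"])
    np.add.at(dmu, elec.j, w[:, None] * g["mub"])
    np.add.at(dth, elec.i, w[:, None, None] * g["tha"])
    np.add.at(dth, elec.j, w[:, None, None] * g["thb"])

    h = 1e-5
    for ctx in contexts:
        if not ctx.alfs:
            continue  # frame-free moments do not vary with geometry
        idx = np.array(ctx.indices)
        base = ctx.sub.positions
        for local_a in range(len(idx)):
            for d in range(3):
                pp = base.copy()
                pp[local_a, d] += h
                qp, mup, thp = _molecule_moments_at(ctx, model, pp)
                pp[local_a, d] -= 2 * h
                qm, mum, thm = _molecule_moments_at(ctx, model, pp)
                de = (
                    np.dot(dq[idx], qp - qm)
                    + np.sum(dmu[idx] * (mup - mum))
                    + np.sum(dth[idx] * (thp - thm))
                ) / (2.0 * h)
                out[idx[local_a], d] -= de
    return out


def molecular_dipole(structure: Structure, model: EnergyModel) -> np.ndarray:
    """Total dipole (e Å): point charges times positions plus atomic dipoles.

    Well defined (origin independent) for neutral systems; the charge origin
    is the centroid.
    """
    _, moments = _evaluate_molecules(structure, model)
    pos = structure.positions
    origin = pos.mean(axis=0)
    return np.einsum("i,ia->a", moments.charges, pos - origin) + moments.dipoles.sum(axis=0)


def lattice_energy(e_super: float, n_molecules: int, e_mono: float) -> float:
    """E_latt = E_super / N - E_mono, kJ/mol per molecule."""
    if n_molecules <= 0:
        raise ValueError("molecule count must be positive")
    return e_super / n_molecules - e_mono


def relative_lattice_energies(energies: dict, reference: str) -> dict:
    """Each phase's lattice energy minus the reference phase's, kJ/mol."""
    if reference not in energies:
        raise KeyError(f"reference phase {reference!r} not in {sorted(energies)}")
    ref = energies[reference]
    return {phase: e - ref for phase, e in energies.items()}


def lj_params_from_text(text) -> LJParams:
    """Parse the plain-text pair table: one ``el_i el_j epsilon sigma`` per line.

    Units kJ/mol and Å; ``#`` starts a comment.  The inverse of
    :func:`lj_params_to_text`.
    """
    pairs = {}
    for ln, line in enumerate(str(text).splitlines(), start=1):
        body = line.split("#")[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 4:
            raise ValueError(f"line {ln}: expected 'el_i el_j epsilon sigma'")
        pairs[(parts[0], parts[1])] = (float(parts[2]), float(parts[3]))
    return LJParams(pairs)


def lj_params_to_text(lj: LJParams) -> str:
    lines = ["# element_i element_j epsilon(kJ/mol) sigma(Å)"]
    for key, (eps, sigma) in sorted(lj._table.items(), key=lambda kv: sorted(kv[0])):
        els = sorted(key)
        a, b = (els[0], els[0]) if len(els) == 1 else els
        lines.append(f"{a} {b} {eps:.10g} {sigma:.10g}")
    return "\n".join(lines) + "\n"
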