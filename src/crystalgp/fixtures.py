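"""Synthetic water-like training data and toy molecular crystals.

This module replaces the upstream quantum-chemistry labelling pipeline with an
analytic three-atom potential energy surface whose per-atom energy partition
sums *exactly* to the molecular energy, plus a geometry-linear charge/multipole
model.  It makes no claim to emulate the physics of a real atomic energy
decomposition — only its data shape — which is all the regression and lattice
dynamics machinery depends on.

The PES is a quadratic form in the internal coordinates (two O-H bond
stretches and the H-O-H bend) with stretch-stretch and stretch-bend couplings;
the force constants are chosen so harmonic frequencies land in the water-like
100-4000 cm^-1 window, making unit errors conspicuous.

Everything stochastic is driven by one seed argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import gpr
from .alf import compute_alf, cyclic_mask, featurize
from .energy import EnergyModel, GPRIntraModel, LJParams
from .gpr import LabelledDataset
from .structures import Atom, Lattice, Structure

__all__ = [
    "ToyPESParams",
    "toy_monomer",
    "toy_energy",
    "AnalyticIntraModel",
    "sample_geometries",
    "make_labelled_datasets",
    "train_monomer_model",
    "default_lj",
    "build_toy_crystal",
    "end_to_end_fixture",
]


@dataclass
class ToyPESParams:
    """Parameters of the analytic monomer surface and its label partition.

    Force constants give OH-stretch modes near 3700 cm^-1 and a bend near
    1600 cm^-1.  ``partition`` are the static per-atom shares of the molecular
    energy (order O, H1, H2; they sum to 1); ``redistribution`` adds a smooth
    geometry-dependent reshuffle that sums identically to zero.  Charges are
    equilibrium values plus a linear response to the internal displacements;
    the oxygen also carries a small local-frame dipole and quadrupole.
    """

    r0: float = 0.9572  # Å
    theta0: float = math.radians(104.52)
    k_r: float = 4600.0  # kJ/mol/Å^2
    k_theta: float = 320.0  # kJ/mol/rad^2
    k_rr: float = -100.0
    k_rtheta: float = 90.0
    e_ref: float = -500.0  # kJ/mol
    partition: tuple = (0.5, 0.25, 0.25)
    redistribution: float = 10.0  # kJ/mol/Å
    q_h: float = 0.32  # e
    dq_dr: float = 0.10  # e/Å
    dq_dtheta: float = -0.05  # e/rad
    dipole_o: tuple = (0.06, 0.04, 0.0)  # e Å, oxygen ALF frame
    ddipole_dr: float = 0.02
    quad_o: tuple = (0.02, -0.008)  # e Å^2: local (xx, yy); zz = -(xx+yy)

    def __post_init__(self):
        if abs(sum(self.partition) - 1.0) > 1e-12:
            raise ValueError("partition fractions must sum to 1")
        if self.k_r <= 0 or self.k_theta <= 0:
            raise ValueError("diagonal force constants must be positive")
        hess = np.array([
            [self.k_r, self.k_rr, self.k_rtheta],
            [self.k_rr, self.k_r, self.k_rtheta],
            [self.k_rtheta, self.k_rtheta, self.k_theta],
        ])
        if np.any(np.linalg.eigvalsh(hess) <= 0):
            raise ValueError("internal-coordinate Hessian is not positive definite")


def toy_monomer(params: ToyPESParams | None = None) -> Structure:
    """Equilibrium monomer (O, H1, H2) in its canonical plane."""
    p = params or ToyPESParams()
    return Structure(atoms=[
        Atom("O", [0.0, 0.0, 0.0], molecule_id=0),
        Atom("H", [p.r0, 0.0, 0.0], molecule_id=0),
        Atom("H", [p.r0 * math.cos(p.theta0), p.r0 * math.sin(p.theta0), 0.0], molecule_id=0),
    ])


def _internals(structure: Structure):
    pos = structure.positions
    v1 = pos[1] - pos[0]
    v2 = pos[2] - pos[0]
    r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
    theta = math.acos(float(np.clip(np.dot(v1, v2) / (r1 * r2), -1.0, 1.0)))
    return r1, r2, theta


def _pes_energy(p: ToyPESParams, r1, r2, theta):
    d1, d2, dt = r1 - p.r0, r2 - p.r0, theta - p.theta0
    return (
        p.e_ref
        + 0.5 * p.k_r * (d1 * d1 + d2 * d2)
        + 0.5 * p.k_theta * dt * dt
        + p.k_rr * d1 * d2
        + p.k_rtheta * (d1 + d2) * dt
    )


def _charges(p: ToyPESParams, r1, r2, theta):
    d1, d2, dt = r1 - p.r0, r2 - p.r0, theta - p.theta0
    q1 = p.q_h + p.dq_dr * d1 + p.dq_dtheta * dt
    q2 = p.q_h + p.dq_dr * d2 + p.dq_dtheta * dt
    return -(q1 + q2), q1, q2  # order O, H1, H2


def toy_energy(structure: Structure, params: ToyPESParams | None = None):
    """Labels of one monomer geometry.

    Returns a dict with ``e_total`` (kJ/mol), per-atom ``energies`` summing to
    e_total exactly, ``charges`` (e, summing to zero), local-frame ``dipoles``
    (e Å) and traceless ``quadrupoles`` (e Å^2), atom order (O, H1, H2).
    """
    p = params or ToyPESParams()
    if len(structure) != 3:
        raise ValueError("toy PES is defined for 3-atom monomers")
    r1, r2, theta = _internals(structure)
    e_total = _pes_energy(p, r1, r2, theta)
    d1, d2 = r1 - p.r0, r2 - p.r0
    f_o, f_h1, f_h2 = p.partition
    c = p.redistribution
    energies = np.array([
        f_o * e_total + c * (d1 + d2),
        f_h1 * e_total - c * d1,
        f_h2 * e_total - c * d2,
    ])
    q_o, q_h1, q_h2 = _charges(p, r1, r2, theta)
    dip = np.zeros((3, 3))
    dip[0] = np.array(p.dipole_o) + np.array([p.ddipole_dr * (d1 + d2), 0.0, 0.0])
    xx, yy = p.quad_o
    quad = np.zeros((3, 3, 3))
    quad[0] = np.diag([xx, yy, -(xx + yy)])
    return {
        "e_total": float(e_total),
        "energies": energies,
        "charges": np.array([q_o, q_h1, q_h2]),
        "dipoles": dip,
        "quadrupoles": quad,
    }


class AnalyticIntraModel:
    """Exact intramolecular model over ALF features — the training-free oracle.

    Each atom's features are inverted back to the molecule's internal
    coordinates (for the hydrogens the second bond length and the central
    angle follow from the feature triangle by the law of cosines), so the
    per-atom energies, charges and moments of :func:`toy_energy` are
    reproduced exactly without any regression.
    """

    n_atoms = 3

    def __init__(self, params: ToyPESParams | None = None):
        self.params = params or ToyPESParams()

    def _internals_from(self, atom_index, feats):
        f0, f1, f2 = float(feats[0]), float(feats[1]), float(feats[2])
        if atom_index == 0:  # oxygen: features are (r1, r2, theta) directly
            return f0, f1, f2, None
        # hydrogen k: f0 = r(Hk-O), f1 = r(Hk-Hother), f2 = angle at Hk
        r_own = f0
        r_other_sq = f0 * f0 + f1 * f1 - 2.0 * f0 * f1 * math.cos(f2)
        r_other = math.sqrt(max(r_other_sq, 1e-12))
        cos_theta = (r_own**2 + r_other**2 - f1 * f1) / (2.0 * r_own * r_other)
        theta = math.acos(float(np.clip(cos_theta, -1.0, 1.0)))
        return r_own, r_other, theta, atom_index

    def atomic_energies(self, features):
        p = self.params
        out = np.zeros(3)
        for a, feats in enumerate(features):
            if a == 0:
                r1, r2, theta, _ = self._internals_from(0, feats)
                e = _pes_energy(p, r1, r2, theta)
                out[0] = p.partition[0] * e + p.redistribution * ((r1 - p.r0) + (r2 - p.r0))
            else:
                r_own, r_other, theta, _ = self._internals_from(a, feats)
                # the PES is symmetric in (r1, r2) so the assignment is immaterial
                e = _pes_energy(p, r_own, r_other, theta)
                out[a] = p.partition[a] * e - p.redistribution * (r_own - p.r0)
        return out

    def atomic_energy_feature_grads(self, features):
        grads = []
        h = 1e-6
        for a, feats in enumerate(features):
            g = np.zeros(len(feats))
            for d in range(len(feats)):
                fp = np.array(feats, dtype=float)
                fm = fp.copy()
                fp[d] += h
                fm[d] -= h
                # drop e_ref before differencing to avoid cancellation noise
                g[d] = (self._energy_of(a, fp) - self._energy_of(a, fm)) / (2.0 * h)
            grads.append(g)
        return grads

    def _energy_of(self, a, feats):
        p = self.params
        if a == 0:
            r1, r2, theta, _ = self._internals_from(0, feats)
            return (p.partition[0] * (_pes_energy(p, r1, r2, theta) - p.e_ref)
                    + p.redistribution * ((r1 - p.r0) + (r2 - p.r0)))
        r_own, r_other, theta, _ = self._internals_from(a, feats)
        return (p.partition[a] * (_pes_energy(p, r_own, r_other, theta) - p.e_ref)
                - p.redistribution * (r_own - p.r0))

    def atomic_multipoles_local(self, features):
        p = self.params
        charges = np.zeros(3)
        dipoles = np.zeros((3, 3))
        quads = np.zeros((3, 3, 3))
        for a, feats in enumerate(features):
            if a == 0:
                r1, r2, theta, _ = self._internals_from(0, feats)
                q_o, _, _ = _charges(p, r1, r2, theta)
                charges[0] = q_o
                dipoles[0] = np.array(p.dipole_o) + np.array(
                    [p.ddipole_dr * ((r1 - p.r0) + (r2 - p.r0)), 0.0, 0.0]
                )
                xx, yy = p.quad_o
                quads[0] = np.diag([xx, yy, -(xx + yy)])
            else:
                r_own, r_other, theta, _ = self._internals_from(a, feats)
                d_own, dt = r_own - p.r0, theta - p.theta0
                charges[a] = p.q_h + p.dq_dr * d_own + p.dq_dtheta * dt
        return charges, dipoles, quads


def sample_geometries(n, spread=(0.05, 0.12), seed=0, params=None, randomize_pose=True):
    """Seeded Gaussian sampling of monomer internal coordinates.

    ``spread`` = (sigma_r Å, sigma_theta rad); the default widths span a
    high-temperature-like energy window (>= 100 kJ/mol across a few thousand
    samples).  Non-physical draws (r <= 0.3 Å or theta outside (0, pi)) are
    resampled and counted.  Each geometry gets a random rigid rotation and
    translation so downstream invariance is genuinely exercised.
    Returns ``(structures, info)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = params or ToyPESParams()
    rng = np.random.default_rng(seed)
    sigma_r, sigma_t = spread
    structures = []
    rejected = 0
    while len(structures) < n:
        r1 = p.r0 + rng.normal(0.0, sigma_r)
        r2 = p.r0 + rng.normal(0.0, sigma_r)
        theta = p.theta0 + rng.normal(0.0, sigma_t)
        if r1 <= 0.3 or r2 <= 0.3 or not 0.0 < theta < math.pi:
            rejected += 1
            continue
        s = Structure(atoms=[
            Atom("O", [0.0, 0.0, 0.0], molecule_id=0),
            Atom("H", [r1, 0.0, 0.0], molecule_id=0),
            Atom("H", [r2 * math.cos(theta), r2 * math.sin(theta), 0.0], molecule_id=0),
        ])
        if randomize_pose:
            R = _random_rotation(rng)
            t = rng.uniform(-5.0, 5.0, size=3)
            s.positions = s.positions @ R.T + t
        structures.append(s)
    return structures, {"rejected": rejected, "seed": seed, "spread": tuple(spread)}


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_labelled_datasets(structures, params=None):
    """Per-atom, per-property labelled datasets from monomer geometries.

    Returns a dict: ``energy`` and ``charge`` map to a list of three
    LabelledDataset (atom order O, H1, H2); ``dipole`` maps to three lists of
    three (local-frame components x, y, z); ``quadrupole`` to three lists of
    five (xx, yy, xy, xz, yz).  Energy datasets carry ``e_wfn`` (the molecular
    energy) and ``e_iqa_sum`` (sum of atomic labels) per geometry — identical
    by construction for clean fixture data, so the recovery error is zero.
    """
    p = params or ToyPESParams()
    alfs = [compute_alf(structures[0], a) for a in range(3)]
    feats = {a: [] for a in range(3)}
    labels = {"energy": {a: [] for a in range(3)}, "charge": {a: [] for a in range(3)},
              "dipole": {a: [[] for _ in range(3)] for a in range(3)},
              "quadrupole": {a: [[] for _ in range(5)] for a in range(3)}}
    e_wfn, e_sum = [], []
    for s in structures:
        lab = toy_energy(s, p)
        e_wfn.append(lab["e_total"])
        e_sum.append(float(lab["energies"].sum()))
        for a in range(3):
            feats[a].append(featurize(s, a, alfs[a]))
            labels["energy"][a].append(lab["energies"][a])
            labels["charge"][a].append(lab["charges"][a])
            for c in range(3):
                labels["dipole"][a][c].append(lab["dipoles"][a][c])
            qd = lab["quadrupoles"][a]
            for c, val in enumerate((qd[0, 0], qd[1, 1], qd[0, 1], qd[0, 2], qd[1, 2])):
                labels["quadrupole"][a][c].append(val)
    e_wfn, e_sum = np.array(e_wfn), np.array(e_sum)
    ids = np.arange(len(structures))
    out = {"energy": [], "charge": [], "dipole": [], "quadrupole": [], "alfs": alfs}
    for a in range(3):
        X = np.array(feats[a])
        out["energy"].append(LabelledDataset(X, labels["energy"][a], ids, e_wfn, e_sum))
        out["charge"].append(LabelledDataset(X, labels["charge"][a], ids))
        out["dipole"].append([LabelledDataset(X, labels["dipole"][a][c], ids) for c in range(3)])
        out["quadrupole"].append(
            [LabelledDataset(X, labels["quadrupole"][a][c], ids) for c in range(5)]
        )
    return out


def _train_one(dataset, sizes, seed, bounds, noise, hyper_kwargs, meta):
    train, internal, external = gpr.stratified_split(dataset, sizes, seed=seed)
    mask = cyclic_mask(train.X.shape[1])
    hp = gpr.optimize_hyperparameters(
        train, internal, bounds=bounds, noise=noise, seed=seed, cyclic=mask,
        **(hyper_kwargs or {}),
    )
    model = gpr.fit(train, hp, cyclic=mask, meta=meta)
    rmse = gpr.validation_rmse(model, external)
    return model, {"external_rmse": rmse, "s_curve": gpr.s_curve(model, external)}


def train_monomer_model(datasets, sizes=(200, 100, 1000), seed=0, bounds=(1e-2, 1e4),
                        noise=1e-10, properties=("energy", "charge", "dipole"),
                        hyper_kwargs=None):
    """Train per-atom GPR models and assemble a :class:`GPRIntraModel`.

    ``datasets`` is the output of :func:`make_labelled_datasets` (after any
    recovery filtering).  Returns ``(intra_model, diagnostics)`` with external
    RMSEs and S-curves per trained model.
    """
    diag = {}
    meta_common = {
        "alf": [(a.center, a.x_axis_atom, a.plane_atom) for a in datasets["alfs"]],
        "feature_order": "r(A_x), r(A_xy), angle, then (r, theta, phi) by atom index",
        "sizes": tuple(sizes),
    }
    energy_models = []
    for a, ds in enumerate(datasets["energy"]):
        m, d = _train_one(ds, sizes, seed + a, bounds, noise, hyper_kwargs,
                          {**meta_common, "property": f"energy/atom{a}"})
        energy_models.append(m)
        diag[f"energy/{a}"] = d
    charge_models = None
    if "charge" in properties:
        charge_models = []
        for a, ds in enumerate(datasets["charge"]):
            m, d = _train_one(ds, sizes, seed + 10 + a, bounds, noise, hyper_kwargs,
                              {**meta_common, "property": f"charge/atom{a}"})
            charge_models.append(m)
            diag[f"charge/{a}"] = d
    dipole_models = None
    if "dipole" in properties:
        dipole_models = []
        for a, comp_sets in enumerate(datasets["dipole"]):
            row = []
            for c, ds in enumerate(comp_sets):
                m, d = _train_one(ds, sizes, seed + 20 + 3 * a + c, bounds, noise,
                                  hyper_kwargs, {**meta_common, "property": f"dipole/atom{a}/{c}"})
                row.append(m)
                diag[f"dipole/{a}/{c}"] = d
            dipole_models.append(row)
    quad_models = None
    if "quadrupole" in properties:
        quad_models = []
        for a, comp_sets in enumerate(datasets["quadrupole"]):
            row = []
            for c, ds in enumerate(comp_sets):
                m, d = _train_one(ds, sizes, seed + 40 + 5 * a + c, bounds, noise,
                                  hyper_kwargs, {**meta_common, "property": f"quadrupole/atom{a}/{c}"})
                row.append(m)
                diag[f"quadrupole/{a}/{c}"] = d
            quad_models.append(row)
    return GPRIntraModel(energy_models, charge_models, dipole_models, quad_models), diag


def default_lj() -> LJParams:
    """Fixture Lennard-Jones table (kJ/mol, Å) for the toy water crystal."""
    return LJParams({
        ("O", "O"): (0.80, 3.00),
        ("O", "H"): (0.30, 2.30),
        ("H", "H"): (0.15, 1.80),
    })


def build_toy_crystal(params=None, a=4.4, n_molecules=2, min_distance=0.8) -> Structure:
    """Toy molecular crystal: monomers on lattice sites of a cubic cell.

    The default arrangement places two monomers related by inversion (so the
    cell carries no net dipole) at (1/4, 1/4, 1/4) and (3/4, 3/4, 3/4) of a
    cubic cell of edge ``a``.  ``n_molecules=1`` gives a single molecule per
    cell (useful for cheap phonon fixtures).
    """
    p = params or ToyPESParams()
    mono = toy_monomer(p)
    centroid = mono.positions.mean(axis=0)
    base = mono.positions - centroid
    lattice = Lattice(np.eye(3) * a)
    if n_molecules == 1:
        sites = [(np.array([0.5, 0.5, 0.5]), np.eye(3))]
    elif n_molecules == 2:
        sites = [
            (np.array([0.25, 0.25, 0.25]), np.eye(3)),
            (np.array([0.75, 0.75, 0.75]), -np.eye(3)),  # inversion image
        ]
    else:
        raise ValueError("supported cells carry 1 or 2 molecules")
    atoms = []
    for mol_id, (frac, op) in enumerate(sites):
        center = lattice.cartesian(frac)
        for el, pos in zip(mono.elements, base):
            atoms.append(Atom(el, center + pos @ op.T, molecule_id=mol_id))
    s = Structure(atoms=atoms, lattice=lattice, periodic=True,
                  meta={"molecule_id_source": "explicit"})
    _check_overlap(s, min_distance)
    return s


# Relaxed reference geometry of the default toy crystal (two inversion-related
# monomers, default PES + LJ + rank-1 electrostatics at 5 Å cutoff), obtained
# with the staged zero-Kelvin optimizer at tightened thresholds.  Starting the
# end-to-end chain here keeps the relaxation stage short while still exercising
# it; the structure is dynamically stable (checked on a 3x3x2 q-mesh).
TOY_CRYSTAL_CELL = np.array([
    [3.0613188718, 0.0, 0.0],
    [-0.27884161821, 3.0803315840, 0.0],
    [0.0, 0.0, 4.8155547120],
])
TOY_CRYSTAL_FRAC = np.array([
    [0.2489233624, 0.2622568349, 0.25],
    [0.5656704198, 0.2573839284, 0.25],
    [0.2386820709, 0.5750190073, 0.25],
    [0.7510766377, 0.7377431650, 0.75],
    [0.4343295802, 0.7426160715, 0.75],
    [0.7613179291, 0.4249809926, 0.75],
])


def relaxed_toy_crystal() -> Structure:
    """The pre-relaxed two-molecule toy crystal (atom order O H H, O H H)."""
    lattice = Lattice(TOY_CRYSTAL_CELL.copy())
    elements = ["O", "H", "H", "O", "H", "H"]
    atoms = [
        Atom(el, lattice.cartesian(f), molecule_id=i // 3)
        for i, (el, f) in enumerate(zip(elements, TOY_CRYSTAL_FRAC))
    ]
    return Structure(atoms=atoms, lattice=lattice, periodic=True,
                     meta={"molecule_id_source": "explicit"})


def _check_overlap(structure, min_distance):
    from .energy import _pair_list

    i, j, rvec = _pair_list(structure, cutoff=max(min_distance * 4, 3.0))
    if len(i):
        d = np.linalg.norm(rvec, axis=1)
        if d.min() < min_distance:
            raise ValueError(
                f"overlapping molecules: intermolecular distance {d.min():.3f} Å"
            )


def toy_energy_model(intra=None, params=None, rank=1, cutoff=5.0, taper_width=1.0) -> EnergyModel:
    """EnergyModel wired for the toy crystal (reduced cutoffs matching cell size)."""
    return EnergyModel(
        intra=intra or AnalyticIntraModel(params),
        lj=default_lj(),
        elec_cutoff=cutoff,
        vdw_cutoff=cutoff,
        rank=rank,
        taper_width=taper_width,
    )


def end_to_end_fixture(seed=0, n_samples=2000, sizes=(200, 100, 1000),
                       temperatures=(10.0, 50.0, 100.0),
                       scales=(0.985, 1.0, 1.015, 1.03, 1.045, 1.06, 1.075),
                       hyper_kwargs=None, relax_steps=1200, supercell=(3, 3, 2),
                       mesh=(3, 3, 2)):
    """Run the whole chain on the toy system and return the bundle.

    sample -> recovery filter -> stratified 200/100/1000 split -> per-atom GPR
    training -> crystal relaxation -> harmonic phonons -> quasi-harmonic
    volume scan and equation-of-state fits.  Every stage's output is kept in
    the returned dict for inspection and testing.

    The relaxation starts from the pre-relaxed reference of the analytic
    potential and uses thresholds well below the production defaults: the
    phonon stage needs residual forces far smaller than the 2.2 kJ/mol/Å
    optimisation gauge, otherwise soft lattice modes show up imaginary.

    Study conditions: the toy crystal destabilises under a few percent of
    compression (a pressure-induced soft mode sits close to the equilibrium
    volume), so the scan window is asymmetric (-1.5% to +7.5%, seven volumes
    bracketing 1.0) and the temperature grid stops at 100 K — above that the
    quasi-harmonic minimum runs into the dynamical-stability edge and the
    volume bracket no longer contains it.
    """
    from . import optimize, phonons, qha
    from .energy import forces as model_forces, total_energy

    p = ToyPESParams()
    geoms, sample_info = sample_geometries(n_samples, seed=seed, params=p)
    datasets = make_labelled_datasets(geoms, p)
    filtered_energy = [gpr.recovery_filter(ds, threshold=1.0) for ds in datasets["energy"]]
    datasets["energy"] = filtered_energy
    intra, diag = train_monomer_model(
        datasets, sizes=sizes, seed=seed, hyper_kwargs=hyper_kwargs,
    )
    model = toy_energy_model(intra=intra, params=p, rank=1)

    crystal = relaxed_toy_crystal()
    tight = optimize.ConvergenceThresholds(0.02, 0.012, 1.8e-4, 1.2e-4, 2e-7)
    plan = optimize.StagePlan(stages=[
        optimize.Stage("atoms", max_steps=relax_steps),
        optimize.Stage("atoms+lengths", max_steps=relax_steps),
        optimize.Stage("atoms+lengths+angles", max_steps=2 * relax_steps),
    ])
    relaxed, trajectory, converged = optimize.relax(
        crystal, model=model, plan=plan, thresholds=tight, cell_step_every=4,
        cell_rate=1e-3,
    )

    energy_fn = lambda s: total_energy(s, model).e_total
    force_fn = lambda s: model_forces(s, model)
    fc = phonons.finite_displacement_force_constants(relaxed, supercell, force_fn)
    gamma = phonons.modes_at(fc, (0.0, 0.0, 0.0))
    curves = phonons.free_energy_curve(fc, temperatures, mesh=mesh)

    scan_log = []
    fv, details = qha.volume_scan(
        relaxed, scales, temperatures, energy_fn=energy_fn, force_fn=force_fn,
        supercell=supercell, mesh=mesh,
        relax_kwargs={
            "plan": optimize.StagePlan(stages=[
                optimize.Stage("atoms", max_steps=relax_steps),
            ]),
            "thresholds": tight,
        },
        log=scan_log,
    )
    eos = [qha.fit_birch_murnaghan(pts) for pts in fv.values()]
    return {
        "params": p,
        "sample_info": sample_info,
        "datasets": datasets,
        "intra_model": intra,
        "training_diagnostics": diag,
        "energy_model": model,
        "crystal": crystal,
        "relaxed": relaxed,
        "relax_converged": converged,
        "relax_trajectory": trajectory,
        "force_constants": fc,
        "gamma_modes": gamma,
        "free_energy_curves": curves,
        "volume_scan": fv,
        "volume_scan_log": scan_log,
        "eos_fits": eos,
    }
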