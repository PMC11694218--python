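"""Finite-displacement harmonic phonons and thermodynamics.

Pipeline: displace every atom of the provided cell by +-u along x, y, z (6N
single-point force calculations, no symmetry reduction), assemble second-order
force constants by central differences, enforce the acoustic sum rule, Bloch-
transform to the dynamical matrix at arbitrary wavevectors, and diagonalise
for frequencies (cm^-1; imaginary modes are reported as negative numbers) and
mass-weighted eigenvectors.  On top of the frequencies: dispersion along
paths, a Gaussian-broadened density of states on a regular Gamma-centred
q-mesh, and the harmonic Helmholtz free energy / vibrational internal energy /
entropy per unit cell.

The cell handed to ``generate_displacements`` may be a primitive cell
extracted from a relaxed supercell: forces are then evaluated on supercells
built from it, which cuts the displacement count by the supercell factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CM1_TO_KJMOL, KB, SQRT_EV_TO_CM1
from .structures import Structure, build_supercell

__all__ = [
    "DisplacementTask",
    "ForceConstants",
    "PhononModes",
    "DoS",
    "ImaginaryModeError",
    "generate_displacements",
    "displaced_supercell",
    "finite_displacement_force_constants",
    "assemble_force_constants",
    "dynamical_matrix",
    "phonon_frequencies",
    "band_structure",
    "density_of_states",
    "mesh_frequencies",
    "helmholtz_free_energy",
    "free_energy_curve",
]

DEFAULT_AMPLITUDE = 5e-3  # Å


class ImaginaryModeError(ValueError):
    """Imaginary (negative) frequencies where real ones are required."""


@dataclass(frozen=True)
class DisplacementTask:
    atom: int
    direction: int  # 0, 1, 2 for x, y, z
    sign: int  # +1 or -1
    amplitude: float = DEFAULT_AMPLITUDE


def generate_displacements(cell: Structure, amplitude: float = DEFAULT_AMPLITUDE):
    """All 6N single-atom displacement tasks (+-x, +-y, +-z per atom)."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if not cell.periodic:
        raise ValueError("phonon displacements need a periodic cell")
    return [
        DisplacementTask(atom=k, direction=d, sign=s, amplitude=amplitude)
        for k in range(len(cell))
        for d in range(3)
        for s in (+1, -1)
    ]


def displaced_supercell(cell: Structure, expansion, task: DisplacementTask) -> Structure:
    """Supercell with the task's atom (in the first cell image) displaced."""
    sc = build_supercell(cell, expansion)
    sc.atoms[task.atom].position[task.direction] += task.sign * task.amplitude
    return sc


@dataclass
class ForceConstants:
    """Phi[(0 k a), (l' k' b)] in kJ/mol/Å², supercell-mapped.

    ``phi`` has shape (n_b, 3, n_cells, n_b, 3); ``cell_offsets`` (n_cells, 3)
    are the integer offsets of each cell image, first entry (0, 0, 0);
    ``cell`` is the generating unit cell.
    """

    phi: np.ndarray
    cell_offsets: np.ndarray
    cell: Structure
    expansion: tuple

    @property
    def n_atoms(self):
        return self.phi.shape[0]


def assemble_force_constants(cell, expansion, task_forces, tasks,
                             symmetrize=True, acoustic_sum_rule=True) -> ForceConstants:
    """Central-difference force constants from the 6N task force sets.

    ``task_forces`` maps each task to the (n_super, 3) force array of its
    displaced supercell.  Phi = -(F(+u) - F(-u)) / (2u), pairs symmetrized,
    then the self-terms are adjusted so every row of the force-constant matrix
    sums to zero (acoustic sum rule).
    """
    n1, n2, n3 = expansion
    n_b = len(cell)
    n_cells = n1 * n2 * n3
    offsets = np.array([(i, j, k) for i in range(n1) for j in range(n2) for k in range(n3)])
    phi = np.zeros((n_b, 3, n_cells, n_b, 3))
    by_key = {}
    for task, f in zip(tasks, task_forces):
        f = np.asarray(f, dtype=float)
        if f.shape != (n_cells * n_b, 3):
            raise ValueError(f"force array for {task} has shape {f.shape}")
        by_key[(task.atom, task.direction, task.sign)] = (f, task.amplitude)
    for k in range(n_b):
        for d in range(3):
            try:
                f_plus, u = by_key[(k, d, +1)]
                f_minus, _ = by_key[(k, d, -1)]
            except KeyError:
                missing = [(k, d, s) for s in (+1, -1) if (k, d, s) not in by_key]
                raise ValueError(f"missing forces for displacement tasks {missing}") from None
            deriv = -(f_plus - f_minus) / (2.0 * u)  # (n_super, 3)
            phi[k, d] = deriv.reshape(n_cells, n_b, 3)

    if symmetrize:
        # Phi[(0k),(l'k')] must equal Phi[(0k'),(-l'k)]^T; average the two.
        folded = np.empty_like(phi)
        inv_index = np.empty(n_cells, dtype=int)
        index = {tuple(o): m for m, o in enumerate(offsets)}
        for m, o in enumerate(offsets):
            inv_index[m] = index[(-o[0] % n1, -o[1] % n2, -o[2] % n3)]
        for m in range(n_cells):
            folded[:, :, m] = phi[:, :, inv_index[m]].transpose(2, 3, 0, 1)
        phi = 0.5 * (phi + folded)

    if acoustic_sum_rule:
        row_sum = phi.sum(axis=(2, 3))  # (n_b, 3, 3)
        for k in range(n_b):
            phi[k, :, 0, k, :] -= row_sum[k]
    return ForceConstants(phi, offsets, cell.copy(), (n1, n2, n3))


def finite_displacement_force_constants(cell, expansion, force_fn,
                                        amplitude=DEFAULT_AMPLITUDE, **kwargs) -> ForceConstants:
    """Run the whole displacement workflow with ``force_fn(structure)``."""
    tasks = generate_displacements(cell, amplitude)
    task_forces = [force_fn(displaced_supercell(cell, expansion, t)) for t in tasks]
    return assemble_force_constants(cell, expansion, task_forces, tasks, **kwargs)


@dataclass
class PhononModes:
    q: np.ndarray  # fractional reciprocal coordinates
    frequencies: np.ndarray  # cm^-1, ascending; negative = imaginary
    eigenvectors: np.ndarray  # columns, mass-weighted, complex
    masses: np.ndarray


def _minimum_image_offsets(fc: ForceConstants):
    """Shortest-vector representatives of every (cell image, k', k) pair.

    A supercell-folded offset l' is ambiguous up to supercell translations:
    for Fourier interpolation at arbitrary q the physically meaningful choice
    is the translate(s) minimising |r(l'k') - r(0k)|, with degenerate minima
    sharing the weight.  Returns a list offsets[m][kp][k] of (vectors, weight)
    where ``vectors`` is an (n_img, 3) array of fractional offsets.
    """
    cached = getattr(fc, "_mic_cache", None)
    if cached is not None:
        return cached
    cell_mat = fc.cell.lattice.cell
    tau = fc.cell.fractional_positions()
    n_b = fc.n_atoms
    n1, n2, n3 = fc.expansion
    shifts = np.array([
        (i * n1, j * n2, k * n3)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    ], dtype=float)
    table = []
    for offset in fc.cell_offsets:
        per_kp = []
        for kp in range(n_b):
            per_k = []
            for k in range(n_b):
                cands = offset + shifts + (tau[kp] - tau[k])
                d = np.linalg.norm(cands @ cell_mat, axis=1)
                keep = d < d.min() + 1e-6
                per_k.append((cands[keep], 1.0 / keep.sum()))
            per_kp.append(per_k)
        table.append(per_kp)
    fc._mic_cache = table
    return table


def dynamical_matrix(fc: ForceConstants, q, masses=None) -> np.ndarray:
    """Mass-weighted Bloch sum D(q), Hermitian complex (3 n_b, 3 n_b).

    The phase convention uses atomic positions: exp(2 pi i q . (f(l'k') - f(0k)))
    with f fractional in the unit cell, q in fractional reciprocal coordinates.
    Supercell-folded images are unwrapped to their shortest translates so the
    interpolation is smooth between commensurate wavevectors.
    """
    cell = fc.cell
    if masses is None:
        masses = cell.masses
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    n_b = fc.n_atoms
    q = np.asarray(q, dtype=float)
    inv_sqrt_m = 1.0 / np.sqrt(masses)
    mic = _minimum_image_offsets(fc)
    D = np.zeros((3 * n_b, 3 * n_b), dtype=complex)
    for m in range(len(fc.cell_offsets)):
        for kp in range(n_b):
            for k in range(n_b):
                vectors, weight = mic[m][kp][k]
                phase = weight * np.exp(2j * np.pi * (vectors @ q)).sum()
                D[3 * k:3 * k + 3, 3 * kp:3 * kp + 3] += (
                    inv_sqrt_m[k] * inv_sqrt_m[kp] * phase * fc.phi[k, :, m, kp, :]
                )
    return 0.5 * (D + D.conj().T)


def phonon_frequencies(D, q=(0.0, 0.0, 0.0), masses=None, hermitian_tol=1e-8) -> PhononModes:
    """Frequencies (cm^-1) and eigenvectors of a dynamical matrix.

    Eigenvalues lambda map to nu = sign(lambda) sqrt(|lambda|); a negative nu
    encodes an imaginary mode.
    """
    D = np.asarray(D)
    if np.max(np.abs(D - D.conj().T)) > hermitian_tol:
        raise ValueError("dynamical matrix is not Hermitian")
    evals, evecs = np.linalg.eigh(D)
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * SQRT_EV_TO_CM1
    if masses is None:
        masses = np.ones(D.shape[0] // 3)
    return PhononModes(np.asarray(q, dtype=float), freqs, evecs, np.asarray(masses))


def modes_at(fc: ForceConstants, q, masses=None) -> PhononModes:
    if masses is None:
        masses = fc.cell.masses
    return phonon_frequencies(dynamical_matrix(fc, q, masses), q=q, masses=masses)


def band_structure(fc: ForceConstants, path, n_per_segment=20, masses=None):
    """Modes along straight segments between the given fractional q-points.

    ``path`` is a list of (label, q) pairs; returns (distances, list of
    PhononModes, tick positions) with distances in reciprocal path length.
    """
    if len(path) < 1:
        raise ValueError("empty path")
    qs = [np.asarray(q, dtype=float) for _, q in path]
    points = []
    for a, b in zip(qs[:-1], qs[1:]):
        for t in np.linspace(0.0, 1.0, n_per_segment, endpoint=False):
            points.append(a + t * (b - a))
    points.append(qs[-1])
    if len(qs) == 1:
        points = [qs[0]]
    modes = [modes_at(fc, q, masses) for q in points]
    dists = np.concatenate([[0.0], np.cumsum([np.linalg.norm(b - a) for a, b in zip(points[:-1], points[1:])])])
    ticks = [0.0]
    for a, b in zip(qs[:-1], qs[1:]):
        ticks.append(ticks[-1] + np.linalg.norm(b - a))
    return dists, modes, list(zip([lbl for lbl, _ in path], ticks))


def mesh_frequencies(fc: ForceConstants, mesh=(16, 16, 16), masses=None):
    """Frequencies on a regular Gamma-centred mesh, with uniform weights.

    Returns (freqs, weights, is_gamma): freqs (n_q, 3 n_b) sorted per q,
    weights summing to 1, and a boolean marking the Gamma point.
    """
    n1, n2, n3 = mesh
    if min(n1, n2, n3) < 1:
        raise ValueError("mesh divisions must be positive")
    qs = [
        (i / n1, j / n2, k / n3)
        for i in range(n1)
        for j in range(n2)
        for k in range(n3)
    ]
    freqs = np.array([modes_at(fc, q, masses).frequencies for q in qs])
    weights = np.full(len(qs), 1.0 / len(qs))
    is_gamma = np.array([q == (0.0, 0.0, 0.0) for q in qs])
    return freqs, weights, is_gamma


@dataclass
class DoS:
    frequencies: np.ndarray  # cm^-1 grid
    density: np.ndarray  # states per cm^-1 per unit cell


def density_of_states(fc: ForceConstants, mesh=(16, 16, 16), broadening=10.0,
                      masses=None, n_grid=1000) -> DoS:
    """Gaussian-broadened phonon DoS; the integral equals 3 n_b per unit cell."""
    freqs, weights, _ = mesh_frequencies(fc, mesh, masses)
    flat = freqs.ravel()
    w = np.repeat(weights, freqs.shape[1])
    lo = flat.min() - 5.0 * broadening
    hi = flat.max() + 5.0 * broadening
    grid = np.linspace(lo, hi, n_grid)
    norm = 1.0 / (broadening * np.sqrt(2.0 * np.pi))
    density = np.zeros_like(grid)
    for nu, ww in zip(flat, w):
        density += ww * norm * np.exp(-0.5 * ((grid - nu) / broadening) ** 2)
    return DoS(grid, density)


def helmholtz_free_energy(frequencies, temperature, weights=None):
    """Harmonic (F, U_vib, S_vib) in kJ/mol per cell from mode frequencies.

    ``frequencies`` in cm^-1, all strictly positive (the caller filters the
    Gamma acoustic modes and must not pass imaginary modes); ``weights`` are
    per-mode q-weights (default 1).  F = sum w [h c nu / 2 +
    kB T ln(1 - exp(-h c nu / kB T))]; at T = 0 this is the zero-point energy.
    """
    nu = np.asarray(frequencies, dtype=float).ravel()
    if np.any(nu < 0):
        raise ImaginaryModeError(
            f"{int(np.sum(nu < 0))} negative frequencies passed to the free energy"
        )
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if weights is None:
        weights = np.ones_like(nu)
    w = np.broadcast_to(np.asarray(weights, dtype=float), nu.shape)
    e = nu * CM1_TO_KJMOL  # hbar omega per mode, kJ/mol
    zpe = float(np.sum(w * 0.5 * e))
    if temperature == 0:
        return zpe, zpe, 0.0
    x = e / (KB * temperature)
    with np.errstate(over="ignore"):
        occ = np.where(x < 700, 1.0 / np.expm1(np.clip(x, None, 700)), 0.0)
    f = zpe + float(np.sum(w * KB * temperature * np.log1p(-np.exp(-x))))
    u = zpe + float(np.sum(w * e * occ))
    s = (u - f) / temperature
    return f, u, s


def free_energy_curve(fc: ForceConstants, temperatures, mesh=(16, 16, 16), masses=None,
                      imaginary_tolerance=0.1):
    """F(T), U(T), S(T) per unit cell over a mesh, Gamma acoustics excluded.

    The three lowest-|nu| modes at Gamma (the acoustic translations, pinned to
    zero by the sum rule) are dropped.  Remaining frequencies below
    ``-imaginary_tolerance`` cm^-1 raise; small negatives within the tolerance
    are treated as numerical noise and clamped to the tolerance.  Returns a
    dict with keys T, F, U, S and the count of clamped modes.
    """
    freqs, weights, is_gamma = mesh_frequencies(fc, mesh, masses)
    keep_f, keep_w = [], []
    for fq, w, g in zip(freqs, weights, is_gamma):
        if g:
            order = np.argsort(np.abs(fq))
            fq = np.delete(fq, order[:3])
        keep_f.append(fq)
        keep_w.append(np.full(len(fq), w))
    flat = np.concatenate(keep_f)
    w = np.concatenate(keep_w)
    n_bad = int(np.sum(flat < -imaginary_tolerance))
    if n_bad:
        raise ImaginaryModeError(
            f"{n_bad} imaginary modes below -{imaginary_tolerance} cm^-1; "
            "the structure is dynamically unstable at this volume"
        )
    n_clamped = int(np.sum(flat < imaginary_tolerance))
    flat = np.maximum(flat, imaginary_tolerance)
    out = {"T": np.asarray(temperatures, dtype=float), "F": [], "U": [], "S": [],
           "clamped_modes": n_clamped}
    for T in out["T"]:
        f, u, s = helmholtz_free_energy(flat, T, w)
        out["F"].append(f)
        out["U"].append(u)
        out["S"].append(s)
    out["F"], out["U"], out["S"] = (np.array(out[k]) for k in ("F", "U", "S"))
    return out
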