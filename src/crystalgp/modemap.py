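"""Mode mapping: scan the potential energy along an imaginary-mode eigenvector.

An imaginary phonon mode marks the reference structure as a saddle point.
Displacing the atoms along the mode's eigenvector pattern with mass-weighted
amplitude Q and evaluating the energy traces out (for a genuine instability) a
double well; the minimising distortion can then be re-relaxed into a candidate
new structure and re-tested for dynamical stability.

Q is normalised so that sum_lk m_k |u_lk|^2 = Q^2 (units amu^(1/2) Å): the
curvature of E(Q) at the origin then equals the mode's omega^2 directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phonons import ForceConstants, finite_displacement_force_constants, modes_at
from .structures import Structure, build_supercell

__all__ = ["ModeMap", "map_mode", "locate_and_reoptimize", "mode_displacement"]


@dataclass
class ModeMap:
    amplitudes: np.ndarray  # amu^(1/2) Å
    energies: np.ndarray  # kJ/mol relative to Q = 0
    q: np.ndarray
    band: int
    frequency: float  # cm^-1 at the mapped mode


def _commensurate(q, expansion):
    prod = np.asarray(q, dtype=float) * np.asarray(expansion)
    return np.allclose(prod, np.round(prod), atol=1e-8)


def mode_displacement(fc: ForceConstants, q, band, expansion):
    """Real displacement pattern (n_super, 3) of unit mass-weighted amplitude.

    For q with 2q equivalent to a reciprocal vector (Gamma, zone boundaries)
    the eigenvector can be chosen real and the pattern is cos-like with phase
    origin at the first atom; otherwise the +-q pair is combined as
    sqrt(2) Re[W exp(2 pi i q . (l + tau))].
    """
    if not _commensurate(q, expansion):
        need = [int(np.ceil(1.0 / max(abs(qi), 1e-12))) if qi else 1 for qi in q]
        raise ValueError(
            f"q = {tuple(q)} incommensurate with supercell {tuple(expansion)}; "
            f"minimal commensurate expansion ~ {tuple(need)}"
        )
    modes = modes_at(fc, q)
    w = modes.eigenvectors[:, band].reshape(-1, 3)
    n_b = fc.n_atoms
    masses = fc.cell.masses
    tau = fc.cell.fractional_positions()
    n1, n2, n3 = expansion
    n_cells = n1 * n2 * n3
    offsets = [(i, j, k) for i in range(n1) for j in range(n2) for k in range(n3)]

    two_q_int = np.allclose(2.0 * np.asarray(q) * np.asarray(expansion) % np.asarray(expansion), 0, atol=1e-8) \
        and np.allclose((2.0 * np.asarray(q)) % 1.0, np.round((2.0 * np.asarray(q)) % 1.0), atol=1e-8)
    is_real_point = np.allclose(np.mod(2.0 * np.asarray(q), 1.0), 0.0, atol=1e-8)

    # fix the global phase so the first atom's largest component is real
    flat = w.ravel()
    pivot = flat[np.argmax(np.abs(flat))]
    w = w * np.conj(pivot) / max(abs(pivot), 1e-300)

    disp = np.zeros((n_cells * n_b, 3))
    for c, off in enumerate(offsets):
        phase = np.exp(2j * np.pi * ((np.asarray(off) + tau) @ np.asarray(q)))  # (n_b,)
        for k in range(n_b):
            if is_real_point:
                u = np.real(w[k] * phase[k])
            else:
                u = np.sqrt(2.0) * np.real(w[k] * phase[k])
            disp[c * n_b + k] = u / np.sqrt(masses[k])
    # normalise: sum m u^2 = 1
    m_super = np.tile(masses, n_cells)
    norm = np.sqrt(np.sum(m_super * np.sum(disp**2, axis=1)))
    if norm < 1e-12:
        raise ValueError("mode pattern vanishes on this supercell")
    return disp / norm, modes.frequencies[band]


def map_mode(structure_cell: Structure, fc: ForceConstants, mode, amplitudes,
             energy_fn, expansion) -> ModeMap:
    """Energy profile E(Q) along one mode of the given wavevector and band.

    ``structure_cell`` is the unit cell the force constants belong to;
    energies are evaluated on the commensurate supercell with ``energy_fn``.
    E(0) is subtracted, so the profile is exactly zero at the origin.
    """
    q, band = np.asarray(mode[0], dtype=float), int(mode[1])
    disp, freq = mode_displacement(fc, q, band, expansion)
    ref = build_supercell(structure_cell, expansion)
    e0 = energy_fn(ref)
    amplitudes = np.asarray(amplitudes, dtype=float)
    energies = np.empty_like(amplitudes)
    for i, Q in enumerate(amplitudes):
        s = ref.copy()
        s.positions = ref.positions + Q * disp
        energies[i] = energy_fn(s) - e0 if Q != 0.0 else 0.0
    return ModeMap(amplitudes, energies, q, band, freq)


def default_amplitudes(q_max=3.0, n=21):
    """Symmetric Q grid of ``n`` points over [-q_max, q_max] (amu^(1/2) Å).

    Widen ``q_max`` until the profile's endpoints rise well above any interior
    minimum (about twice the well depth) so the double well is fully captured.
    """
    return np.linspace(-q_max, q_max, n)


def locate_and_reoptimize(mode_map: ModeMap, structure_cell: Structure, expansion,
                          energy_fn, force_fn, relax_plan=None, phonon_mesh=(2, 2, 2),
                          relax_kwargs=None):
    """Relax the minimum of a double-well mode map and re-test stability.

    Requires an interior minimum with negative energy; returns
    ``(relaxed_supercell, report)`` where the report lists the minimising Q,
    the final energy drop, and any remaining imaginary frequencies of the
    relaxed structure (computed on the relaxed supercell itself at Gamma).
    """
    from .optimize import Stage, StagePlan, relax

    e = mode_map.energies
    i_min = int(np.argmin(e))
    if e[i_min] >= 0 or i_min in (0, len(e) - 1):
        raise ValueError("not a double well: no interior minimum below the origin")
    q_star = mode_map.amplitudes[i_min]

    ref = build_supercell(structure_cell, expansion)
    # rebuild the displacement pattern exactly as map_mode used it
    fc = finite_displacement_force_constants(structure_cell, expansion, force_fn)
    disp, _ = mode_displacement(fc, mode_map.q, mode_map.band, expansion)
    start = ref.copy()
    start.positions = ref.positions + q_star * disp
    plan = relax_plan or StagePlan(stages=[Stage("atoms", max_steps=3000)])
    relaxed, trajectory, converged = relax(
        start, plan=plan, energy_fn=energy_fn, force_fn=force_fn,
        **(relax_kwargs or {}),
    )
    fc_new = finite_displacement_force_constants(relaxed, (1, 1, 1), force_fn)
    freqs = []
    n1, n2, n3 = phonon_mesh
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                freqs.append(modes_at(fc_new, (i / n1, j / n2, k / n3)).frequencies)
    freqs = np.concatenate(freqs)
    gamma = modes_at(fc_new, (0.0, 0.0, 0.0)).frequencies
    acoustic = np.sort(np.abs(gamma))[:3]
    n_imag = int(np.sum(freqs < -max(0.1, 10 * acoustic.max())))
    report = {
        "Q_min": float(q_star),
        "energy_drop": float(energy_fn(relaxed) - energy_fn(ref)),
        "converged": converged,
        "imaginary_modes_remaining": n_imag,
        "min_frequency": float(freqs.min()),
    }
    return relaxed, report
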