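"""Quasi-harmonic free energies: volume scans, Birch-Murnaghan fits, Gibbs
surfaces, polymorph ranking and phase boundaries.

The workflow mirrors standard quasi-harmonic practice: relax a crystal, scan a
bracket of volumes (each constrained-relaxed), compute harmonic Helmholtz
curves F(V; T) = E_static(V) + F_vib(V, T), fit a third-order Birch-Murnaghan
equation of state per temperature, and minimise F + pV over volume for the
Gibbs free energy G(T, p).  Phase boundaries are located by bisection on
Delta G(p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sopt

from .constants import GPA_TO_KJMOL_A3
from .phonons import ImaginaryModeError, finite_displacement_force_constants, free_energy_curve

__all__ = [
    "FVPoint",
    "EOSFit",
    "GibbsSurface",
    "birch_murnaghan_energy",
    "birch_murnaghan_pressure",
    "fit_birch_murnaghan",
    "gibbs_energy",
    "volume_scan",
    "rank_phases",
    "phase_boundary",
]


@dataclass
class FVPoint:
    volume: float  # Å^3 per cell
    temperature: float  # K
    free_energy: float  # kJ/mol per cell (static + vibrational)

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("volume must be positive")


def birch_murnaghan_energy(V, F0, V0, B0, Bp):
    """Third-order Birch-Murnaghan F(V); B0 in kJ/mol/Å^3."""
    x = (V0 / np.asarray(V, dtype=float)) ** (2.0 / 3.0)
    f = x - 1.0
    return F0 + 9.0 * V0 * B0 / 16.0 * (f**3 * Bp + f**2 * (6.0 - 4.0 * x))


def birch_murnaghan_pressure(V, V0, B0, Bp):
    """p(V) = -dF/dV of the third-order form, kJ/mol/Å^3."""
    V = np.asarray(V, dtype=float)
    x = (V0 / V) ** (2.0 / 3.0)
    f = x - 1.0
    dF_dx = 9.0 * V0 * B0 / 16.0 * (3.0 * f**2 * Bp + 2.0 * f * (6.0 - 4.0 * x) - 4.0 * f**2)
    dx_dV = -(2.0 / 3.0) * x / V
    return -dF_dx * dx_dV


@dataclass
class EOSFit:
    temperature: float
    F0: float  # kJ/mol per cell
    V0: float  # Å^3
    B0: float  # kJ/mol/Å^3
    Bp: float
    residual: float
    volume_range: tuple = (0.0, np.inf)

    def __post_init__(self):
        if self.V0 <= 0 or self.B0 <= 0:
            raise ValueError(f"unphysical EOS parameters V0={self.V0}, B0={self.B0}")

    @property
    def B0_gpa(self):
        return self.B0 / GPA_TO_KJMOL_A3

    @property
    def extrapolated(self):
        lo, hi = self.volume_range
        return not (lo <= self.V0 <= hi)

    def energy(self, V):
        return birch_murnaghan_energy(V, self.F0, self.V0, self.B0, self.Bp)

    def pressure(self, V):
        return birch_murnaghan_pressure(V, self.V0, self.B0, self.Bp)


def fit_birch_murnaghan(points) -> EOSFit:
    """Least-squares third-order Birch-Murnaghan fit to F(V) points at one T.

    Initial guesses come from a parabola through the three lowest-F points
    (V0 at its vertex, B0 = V0 F'' there) with Bp = 4.
    """
    points = list(points)
    vols = np.array([p.volume for p in points])
    fs = np.array([p.free_energy for p in points])
    temps = {round(p.temperature, 9) for p in points}
    if len(temps) > 1:
        raise ValueError(f"points span multiple temperatures: {sorted(temps)}")
    if len(np.unique(vols)) < 4:
        raise ValueError("Birch-Murnaghan fit needs at least 4 distinct volumes")

    order = np.argsort(fs)[:3]
    coeffs = np.polyfit(vols[order], fs[order], 2)
    vmin, vmax = float(vols.min()), float(vols.max())
    if coeffs[0] > 0:
        v0 = float(np.clip(-coeffs[1] / (2.0 * coeffs[0]), 0.6 * vmin, 1.6 * vmax))
        b0 = max(2.0 * coeffs[0] * v0, 1e-6)
    else:
        v0 = vols[order[0]]
        b0 = max((fs.max() - fs.min()) / (0.01 * v0**2 + 1e-12), 1e-4)
    p0 = np.array([fs.min(), v0, b0, 4.0])

    def resid(p):
        return birch_murnaghan_energy(vols, *p) - fs

    # bounds keep V0 and B0 positive so the 2/3 powers stay real
    lo = [-np.inf, 0.5 * vmin, 1e-10, -5.0]
    hi = [np.inf, 2.0 * vmax, np.inf, 25.0]
    res = sopt.least_squares(resid, p0, method="trf", bounds=(lo, hi),
                             xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000)
    if not res.success:
        raise RuntimeError(
            f"Birch-Murnaghan fit failed: {res.message}; initial guess {p0}"
        )
    F0, V0, B0, Bp = res.x
    return EOSFit(
        temperature=points[0].temperature, F0=F0, V0=V0, B0=B0, Bp=Bp,
        residual=float(np.sqrt(np.mean(res.fun**2))),
        volume_range=(float(vols.min()), float(vols.max())),
    )


@dataclass
class GibbsSurface:
    temperatures: np.ndarray
    pressures: np.ndarray  # GPa
    G: np.ndarray  # (n_T, n_p) kJ/mol per cell
    V_star: np.ndarray  # (n_T, n_p) minimising volumes, Å^3
    n_molecules: int = 1


def _minimise_gibbs(eos: EOSFit, p_gpa: float, range_factor=1.5):
    """V* solving dF/dV = -p, and G = F(V*) + p V*; p in GPa."""
    p = p_gpa * GPA_TO_KJMOL_A3
    lo, hi = eos.volume_range
    span_lo, span_hi = eos.V0 / range_factor, eos.V0 * range_factor
    if lo > 0 and np.isfinite(hi):
        span_lo, span_hi = min(span_lo, lo / range_factor), max(span_hi, hi)

    def g(V):
        return eos.pressure(V) - p  # root where the EOS pressure balances p

    glo, ghi = g(span_lo), g(span_hi)
    if glo * ghi > 0:
        raise ValueError(
            f"Gibbs minimisation at p={p_gpa} GPa leaves the trusted volume window "
            f"[{span_lo:.3g}, {span_hi:.3g}] Å^3"
        )
    v_star = sopt.brentq(g, span_lo, span_hi, xtol=1e-12, rtol=1e-15)
    return float(eos.energy(v_star) + p * v_star), float(v_star)


def gibbs_energy(eos_by_temperature, pressures_gpa, n_molecules=1) -> GibbsSurface:
    """G(T, p) = min_V [F(V; T) + p V] over the fitted EOS per temperature."""
    eos_list = sorted(eos_by_temperature, key=lambda e: e.temperature)
    temps = np.array([e.temperature for e in eos_list])
    ps = np.asarray(pressures_gpa, dtype=float)
    if np.any(ps < 0):
        raise ValueError("pressures must be >= 0")
    G = np.zeros((len(temps), len(ps)))
    V = np.zeros_like(G)
    for i, eos in enumerate(eos_list):
        for j, p in enumerate(ps):
            G[i, j], V[i, j] = _minimise_gibbs(eos, p)
    return GibbsSurface(temps, ps, G, V, n_molecules)


def volume_scan(structure, scales, temperatures, model=None, energy_fn=None,
                force_fn=None, supercell=(2, 2, 2), mesh=(4, 4, 4),
                relax_kwargs=None, log=None):
    """Constrained-relax a bracket of volumes and attach harmonic F(T) to each.

    ``scales`` are volume factors that must bracket 1.0.  Volumes that turn
    out dynamically unstable (imaginary modes on the mesh) are excluded and
    recorded in ``log`` (a list).  Returns ``(fv_points, details)`` where
    ``fv_points`` maps each temperature to a list of FVPoint and ``details``
    carries per-volume static energies and structures.
    """
    from .optimize import constrained_volume_relax

    scales = sorted(float(s) for s in scales)
    if len(set(scales)) < 2 or not (min(scales) < 1.0 + 1e-12 and max(scales) > 1.0 - 1e-12):
        raise ValueError("volume scales must be distinct and bracket 1.0")
    if log is None:
        log = []
    energy_fn, force_fn = _resolve(model, energy_fn, force_fn)
    v_ref = structure.lattice.volume
    fv = {float(t): [] for t in temperatures}
    details = []
    for scale in scales:
        target = v_ref * scale
        relaxed, _, _ = constrained_volume_relax(
            structure, target_volume=target, energy_fn=energy_fn,
            force_fn=force_fn, **(relax_kwargs or {}),
        )
        e_static = energy_fn(relaxed)
        try:
            fc = finite_displacement_force_constants(relaxed, supercell, force_fn)
            curves = free_energy_curve(fc, temperatures, mesh=mesh)
        except ImaginaryModeError as exc:
            log.append(f"volume scale {scale:g} excluded: {exc}")
            continue
        for t, f_vib in zip(curves["T"], curves["F"]):
            fv[float(t)].append(FVPoint(target, float(t), e_static + float(f_vib)))
        details.append({"scale": scale, "volume": target, "structure": relaxed,
                        "static_energy": e_static})
    usable = min(len(v) for v in fv.values()) if fv else 0
    if usable < 4:
        raise ValueError(
            f"only {usable} usable volumes after stability screening; "
            "the equation-of-state fit is under-determined"
        )
    return fv, details


def _resolve(model, energy_fn, force_fn):
    if energy_fn is not None and force_fn is not None:
        return energy_fn, force_fn
    from .energy import forces as _forces, total_energy as _total

    return (lambda s: _total(s, model).e_total), (lambda s: _forces(s, model))


def rank_phases(free_energies: dict, reference: str, temperatures=None):
    """Per-phase energy curves relative to a reference, with crossings.

    ``free_energies`` maps phase name -> array F(T) (or G(T)) per molecule on
    a common temperature grid.  Returns (deltas, crossings): deltas maps phase
    -> F_phase - F_ref; crossings maps phase -> list of crossing temperatures
    (linear interpolation between grid points).
    """
    if reference not in free_energies:
        raise KeyError(f"reference phase {reference!r} missing")
    ref = np.asarray(free_energies[reference], dtype=float)
    deltas, crossings = {}, {}
    for phase, curve in free_energies.items():
        curve = np.asarray(curve, dtype=float)
        if curve.shape != ref.shape:
            raise ValueError(f"phase {phase!r} grid mismatch")
        d = curve - ref
        deltas[phase] = d
        cross = []
        if temperatures is not None:
            t = np.asarray(temperatures, dtype=float)
            # crossings are transitions between strictly negative and strictly
            # positive stretches; isolated exact zeros on the grid are passed
            # through, identically-zero curves report none
            nz = np.flatnonzero(d)
            for a, b in zip(nz[:-1], nz[1:]):
                if d[a] * d[b] < 0:
                    frac = d[a] / (d[a] - d[b])
                    cross.append(float(t[a] + frac * (t[b] - t[a])))
        crossings[phase] = cross
    return deltas, crossings


def phase_boundary(surface_a: GibbsSurface, surface_b: GibbsSurface,
                   p_window=None, tol_gpa=1e-4, log=None):
    """Transition pressures p*(T) where G_A(T, p) = G_B(T, p).

    Both surfaces must share the temperature grid.  Delta G is evaluated per
    molecule.  Temperatures without a sign change inside the pressure window
    are omitted (and recorded in ``log``).  Returns (T, p*) arrays.
    """
    if not np.allclose(surface_a.temperatures, surface_b.temperatures):
        raise ValueError("temperature grids differ")
    if log is None:
        log = []
    p_grid = surface_a.pressures
    if p_window is None:
        p_window = (float(p_grid.min()), float(p_grid.max()))

    def dg_interp(i):
        da = surface_a.G[i] / surface_a.n_molecules
        db = surface_b.G[i] / surface_b.n_molecules
        return lambda p: np.interp(p, p_grid, da - db)

    out_t, out_p = [], []
    for i, T in enumerate(surface_a.temperatures):
        dg = dg_interp(i)
        lo, hi = p_window
        if not dg(lo) * dg(hi) < 0:  # requires a strict sign change
            log.append(f"T = {T:g} K: no sign change of Delta G in [{lo}, {hi}] GPa")
            continue
        while hi - lo > tol_gpa:
            mid = 0.5 * (lo + hi)
            if dg(lo) * dg(mid) <= 0:
                hi = mid
            else:
                lo = mid
        out_t.append(float(T))
        out_p.append(0.5 * (lo + hi))
    return np.array(out_t), np.array(out_p)
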