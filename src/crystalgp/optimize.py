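"""Zero-Kelvin crystal relaxation with staged degree-of-freedom release.

Atoms follow their forces quasi-statically: each step moves every atom along
its force with the displacement capped at the distance the atom could cover in
one timestep at a 10 K thermal speed (per-atom interpretation), and a step
that would raise the energy is rescaled until it descends.  Cell degrees of
freedom are released in stages — atoms only, then cell lengths, then angles —
with the cell relaxed by steepest descent on the enthalpy E + pV using central
finite differences of the lattice parameters (atoms ride affinely, fractional
coordinates fixed).

Convergence requires five gauges simultaneously on the same step: max and RMS
force below 2.2 and 1.5 kJ/mol/Å, max and RMS step displacement below 1.8e-3
and 1.2e-3 Å, and the per-molecule energy change below 2e-5 kJ/mol (all strict
inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATM_TO_KJMOL_A3, FORCE_OVER_MASS_TO_ACC, thermal_speed
from .structures import Lattice, Structure

__all__ = [
    "ConvergenceGauges",
    "ConvergenceThresholds",
    "Stage",
    "StagePlan",
    "zero_kelvin_displacement",
    "check_convergence",
    "relax",
    "constrained_volume_relax",
]

_STAGE_DOF = ("atoms", "atoms+lengths", "atoms+lengths+angles")


@dataclass
class ConvergenceGauges:
    max_force: float
    rms_force: float
    max_disp: float
    rms_disp: float
    dE: float

    def __post_init__(self):
        for name in ("max_force", "rms_force", "max_disp", "rms_disp", "dE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rms_force > self.max_force + 1e-12 or self.rms_disp > self.max_disp + 1e-12:
            raise ValueError("RMS gauge exceeds max gauge")


@dataclass
class ConvergenceThresholds:
    max_force: float = 2.2  # kJ/mol/Å
    rms_force: float = 1.5  # kJ/mol/Å
    max_disp: float = 1.8e-3  # Å
    rms_disp: float = 1.2e-3  # Å
    dE: float = 2e-5  # kJ/mol per molecule


def check_convergence(gauges: ConvergenceGauges,
                      thresholds: ConvergenceThresholds | None = None) -> bool:
    """All five gauges strictly below their thresholds."""
    t = thresholds or ConvergenceThresholds()
    if min(t.max_force, t.rms_force, t.max_disp, t.rms_disp, t.dE) <= 0:
        raise ValueError("thresholds must be positive")
    return (
        gauges.max_force < t.max_force
        and gauges.rms_force < t.rms_force
        and gauges.max_disp < t.max_disp
        and gauges.rms_disp < t.rms_disp
        and gauges.dE < t.dE
    )


@dataclass
class Stage:
    dof: str = "atoms"  # one of _STAGE_DOF
    max_steps: int = 7000
    timestep: float = 1.0  # fs
    pressure: float = 1.0  # atm

    def __post_init__(self):
        if self.dof not in _STAGE_DOF:
            raise ValueError(f"unknown DoF set {self.dof!r}")


@dataclass
class StagePlan:
    """Ordered stages; DoF sets must be nested in the listed order."""

    stages: list = field(default_factory=lambda: [
        Stage("atoms"), Stage("atoms+lengths"), Stage("atoms+lengths+angles"),
    ])

    def __post_init__(self):
        levels = [_STAGE_DOF.index(s.dof) for s in self.stages]
        if levels != sorted(levels):
            raise ValueError("stage degrees of freedom must be released in nested order")


def zero_kelvin_displacement(forces, masses, timestep, cap_temperature=10.0, velocities=None):
    """Per-atom displacement along the force, speed-capped at ``cap_temperature``.

    Starting from rest, d_i = F_i dt^2 / m_i with the implied per-atom speed
    |d_i| / dt clipped to v_cap(m_i) = sqrt(3 kB T_cap / m_i).  With
    ``velocities`` (Å/fs, updated in place) the step becomes one sweep of
    quenched dynamics: the velocity accumulates along the force, is zeroed on
    any atom moving against its force, and is capped at v_cap — the
    force-following descent with a thermal speed limit.
    """
    forces = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(forces)):
        raise ValueError("non-finite forces")
    masses = np.asarray(masses, dtype=float)
    if velocities is None:
        velocities = np.zeros_like(forces)
    velocities += forces * (timestep * FORCE_OVER_MASS_TO_ACC / masses)[:, None]
    against = np.einsum("ia,ia->i", velocities, forces) < 0.0
    velocities[against] = 0.0
    speeds = np.linalg.norm(velocities, axis=1)
    caps = np.array([thermal_speed(cap_temperature, m) for m in masses])
    over = speeds > caps
    velocities[over] *= (caps[over] / speeds[over])[:, None]
    return velocities * timestep


def _cell_parameters(structure, dof):
    a, b, c, al, be, ga = structure.lattice.parameters
    if dof == "atoms+lengths":
        return np.array([a, b, c])
    return np.array([a, b, c, al, be, ga])


def _apply_cell_parameters(structure, params, dof):
    a, b, c, al, be, ga = structure.lattice.parameters
    if dof == "atoms+lengths":
        a, b, c = params
    else:
        a, b, c, al, be, ga = params
    frac = structure.fractional_positions()
    structure.lattice = Lattice.from_parameters(a, b, c, al, be, ga)
    structure.set_fractional_positions(frac)


def _enthalpy(structure, energy_fn, pressure_atm):
    return energy_fn(structure) + pressure_atm * ATM_TO_KJMOL_A3 * structure.lattice.volume


def _cell_gradient(structure, energy_fn, pressure_atm, dof, rel_step=1e-5):
    params = _cell_parameters(structure, dof)
    grad = np.zeros_like(params)
    for k in range(len(params)):
        h = max(abs(params[k]) * rel_step, 1e-7)
        for sign in (+1, -1):
            trial = structure.copy()
            p = params.copy()
            p[k] += sign * h
            _apply_cell_parameters(trial, p, dof)
            grad[k] += sign * _enthalpy(trial, energy_fn, pressure_atm)
        grad[k] /= 2.0 * h
    return grad


def _resolve_calculator(model, energy_fn, force_fn):
    if energy_fn is not None and force_fn is not None:
        return energy_fn, force_fn
    if model is not None:
        from .energy import forces as _forces, total_energy as _total

        return (lambda s: _total(s, model).e_total), (lambda s: _forces(s, model))
    raise ValueError("pass either model or both energy_fn and force_fn")


def relax(structure: Structure, model=None, plan: StagePlan | None = None,
          energy_fn=None, force_fn=None, thresholds=None, cap_temperature=10.0,
          cell_step_every=5, cell_rate=2e-4, volume_constraint=None,
          divergence_limit=1e3):
    """Staged zero-Kelvin relaxation.

    Returns ``(structure, trajectory, converged)`` where ``trajectory`` is a
    list of per-step dicts (stage, gauges, energy, volume).  ``model`` may be
    any object accepted by the energy module, or explicit ``energy_fn`` /
    ``force_fn`` callables may be supplied (useful for analytic test
    potentials).  ``volume_constraint``, if set, renormalises every cell
    update to that volume.
    """
    energy_fn, force_fn = _resolve_calculator(model, energy_fn, force_fn)
    plan = plan or StagePlan()
    thresholds = thresholds or ConvergenceThresholds()
    s = structure.copy()
    n_mol = max(len(s.molecules()), 1)
    masses = s.masses
    trajectory = []
    e_prev = energy_fn(s)
    e_start = e_prev

    if all(stage.dof == "atoms" for stage in plan.stages):
        # with no cell freedom, vanishing forces already mean convergence
        f0 = force_fn(s)
        gauges0 = ConvergenceGauges(
            float(np.max(np.abs(f0))), float(np.sqrt(np.mean(f0**2))), 0.0, 0.0, 0.0
        )
        if check_convergence(gauges0, thresholds):
            return s, trajectory, True

    last_stage = len(plan.stages) - 1
    for stage_idx, stage in enumerate(plan.stages):
        velocities = np.zeros((len(s), 3))
        rate = cell_rate
        for step in range(stage.max_steps):
            f = force_fn(s)
            disp = zero_kelvin_displacement(
                f, masses, stage.timestep, cap_temperature, velocities
            )
            pos0 = s.positions
            scale = 1.0
            for _ in range(12):
                s.positions = pos0 + scale * disp
                e_new = energy_fn(s)
                if e_new <= e_prev + 1e-12:
                    break
                scale *= 0.5
                velocities[:] = 0.0  # restart the quenched dynamics
            else:
                s.positions = pos0  # no descent possible along the force
                e_new = e_prev
                scale = 0.0
            actual = scale * disp

            if stage.dof != "atoms" and cell_step_every and (step + 1) % cell_step_every == 0:
                grad = _cell_gradient(s, energy_fn, stage.pressure, stage.dof)
                params = _cell_parameters(s, stage.dof)
                trial_params = params - rate * grad * np.maximum(np.abs(params), 1.0)
                before = s.copy()
                _apply_cell_parameters(s, trial_params, stage.dof)
                if volume_constraint is not None:
                    iso = (volume_constraint / s.lattice.volume) ** (1.0 / 3.0)
                    _apply_cell_parameters(
                        s, np.concatenate([np.asarray(trial_params[:3]) * iso, trial_params[3:]]),
                        stage.dof,
                    )
                e_cell = energy_fn(s)
                if e_cell > e_prev + abs(e_prev) * 1e-12 + 1e-9:
                    s = before  # reject uphill cell move, shorten the next one
                    rate = max(rate * 0.5, 1e-8)
                else:
                    actual = actual + (s.positions - (pos0 + actual))
                    e_new = e_cell
                    rate = min(rate * 1.25, 0.1)

            norms = np.linalg.norm(actual, axis=1)
            gauges = ConvergenceGauges(
                float(np.max(np.abs(f))),
                float(np.sqrt(np.mean(f**2))),
                float(np.max(norms)),
                float(np.sqrt(np.mean(norms**2))),
                abs(e_new - e_prev) / n_mol,
            )
            trajectory.append({
                "stage": stage_idx, "step": step, "gauges": gauges,
                "energy": e_new, "volume": s.lattice.volume if s.periodic else None,
            })
            if e_new - e_start > divergence_limit:
                raise RuntimeError(
                    f"energy diverged by {e_new - e_start:.3g} kJ/mol at stage "
                    f"{stage_idx} step {step}"
                )
            e_prev = e_new
            if check_convergence(gauges, thresholds):
                # convergence counts only in the final stage; earlier stages
                # just stop burning steps and hand over to the next one
                if stage_idx == last_stage:
                    return s, trajectory, True
                break
    return s, trajectory, False


def constrained_volume_relax(structure: Structure, model=None, target_volume=None,
                             plan=None, energy_fn=None, force_fn=None, **kwargs):
    """Relax atoms and cell shape at a fixed cell volume.

    The cell is first rescaled isotropically to the target volume; every
    subsequent cell update is projected back onto the constant-volume
    manifold.  The returned structure satisfies |V - target| / target < 1e-8.
    """
    if target_volume is None or target_volume <= 0:
        raise ValueError("target volume must be positive")
    s = structure.copy()
    iso = (target_volume / s.lattice.volume) ** (1.0 / 3.0)
    frac = s.fractional_positions()
    s.lattice = Lattice(s.lattice.cell * iso)
    s.set_fractional_positions(frac)
    plan = plan or StagePlan(stages=[
        Stage("atoms"), Stage("atoms+lengths+angles"),
    ])
    out, trajectory, converged = relax(
        s, model=model, plan=plan, energy_fn=energy_fn, force_fn=force_fn,
        volume_constraint=target_volume, **kwargs,
    )
    if abs(out.lattice.volume - target_volume) / target_volume >= 1e-8:
        iso = (target_volume / out.lattice.volume) ** (1.0 / 3.0)
        frac = out.fractional_positions()
        out.lattice = Lattice(out.lattice.cell * iso)
        out.set_fractional_positions(frac)
    return out, trajectory, converged
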