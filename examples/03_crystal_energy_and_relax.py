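"""Evaluate and relax a toy molecular crystal with the composite potential.

The energy splits into an intramolecular machine-learned (here: analytic)
term, point-multipole electrostatics between molecules, and a 12-6
Lennard-Jones term.  The zero-Kelvin optimizer then follows forces with a
10 K speed cap, releasing cell lengths and angles in stages.
"""

import numpy as np

from crystalgp import optimize
from crystalgp.energy import forces, total_energy
from crystalgp.fixtures import relaxed_toy_crystal, toy_energy_model

model = toy_energy_model(rank=1)  # charges + dipoles, 5 Å molecule-pair cutoff
crystal = relaxed_toy_crystal()
crystal.positions = crystal.positions + np.random.default_rng(1).normal(0, 0.02, (6, 3))

eb = total_energy(crystal, model)
print(f"perturbed crystal:  E_intra={eb.e_intra:.3f}  E_elec={eb.e_elec:.3f}  "
      f"E_LJ={eb.e_lj:.3f}  E_total={eb.e_total:.3f} kJ/mol per cell")

plan = optimize.StagePlan(stages=[
    optimize.Stage("atoms", max_steps=800),
    optimize.Stage("atoms+lengths", max_steps=800),
    optimize.Stage("atoms+lengths+angles", max_steps=1500),
])
tight = optimize.ConvergenceThresholds(0.05, 0.03, 1.8e-4, 1.2e-4, 2e-7)
relaxed, trajectory, converged = optimize.relax(
    crystal, model=model, plan=plan, thresholds=tight, cell_step_every=4, cell_rate=1e-3,
)

eb = total_energy(relaxed, model)
f = forces(relaxed, model)
a, b, c, al, be, ga = relaxed.lattice.parameters
print(f"converged: {converged} after {len(trajectory)} steps")
print(f"cell: a={a:.3f} b={b:.3f} c={c:.3f} Å   alpha={al:.2f} beta={be:.2f} gamma={ga:.2f} deg")
print(f"relaxed energy {eb.e_total:.3f} kJ/mol, residual max force {np.abs(f).max():.3f} kJ/mol/Å")
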