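"""Harmonic phonons of the toy crystal: dispersion, DoS, Helmholtz energy.

Force constants come from 6N single-atom displacements of the unit cell, with
forces evaluated on a 3x3x2 supercell; the acoustic sum rule pins three zero
modes at the zone centre.  The free energy integrates the mode frequencies
over a regular q-mesh.
"""

import numpy as np

from crystalgp import phonons
from crystalgp.energy import forces
from crystalgp.fixtures import relaxed_toy_crystal, toy_energy_model

model = toy_energy_model(rank=1)
crystal = relaxed_toy_crystal()
force_fn = lambda s: forces(s, model)

fc = phonons.finite_displacement_force_constants(crystal, (3, 3, 2), force_fn)
gamma = phonons.modes_at(fc, (0.0, 0.0, 0.0))
print("Gamma frequencies (cm^-1):", np.round(gamma.frequencies, 1))
print("  three acoustic zeros + librations/translations + intramolecular modes")

dists, modes, ticks = phonons.band_structure(
    fc, [("G", (0, 0, 0)), ("X", (0.5, 0, 0)), ("M", (0.5, 0.5, 0))], 10
)
print(f"dispersion sampled at {len(modes)} q-points; "
      f"min/max {min(m.frequencies.min() for m in modes):.1f} / "
      f"{max(m.frequencies.max() for m in modes):.1f} cm^-1")

dos = phonons.density_of_states(fc, mesh=(3, 3, 2), broadening=15.0)
print(f"DoS integral = {np.trapezoid(dos.density, dos.frequencies):.2f} (3 N_b = 18)")

curves = phonons.free_energy_curve(fc, [10.0, 150.0, 300.0], mesh=(3, 3, 2))
for T, F, S in zip(curves["T"], curves["F"], curves["S"]):
    print(f"T = {T:5.0f} K   F_vib = {F:8.3f} kJ/mol/cell   S_vib = {S * 1000:6.3f} J/mol/K")
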