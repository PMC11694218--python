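"""Map a dynamical instability to a lower-energy structure.

A spring crystal is given a quartic double well along one optical mode, so
the reference structure becomes a saddle point with one imaginary frequency.
Scanning the energy along that mode's eigenvector reveals the double well;
relaxing from its minimum yields a distorted structure with no imaginary
modes left - the soft-mode workflow for candidate new polymorphs.
"""

import numpy as np

from crystalgp import phonons
from crystalgp.constants import SQRT_EV_TO_CM1
from crystalgp.model_potentials import BornSpringModel, DoubleWellModel
from crystalgp.modemap import locate_and_reoptimize, map_mode
from crystalgp.structures import Atom, Lattice, Structure

cell = Structure(
    atoms=[Atom("C", [0.0, 0.0, 0.0], molecule_id=0),
           Atom("C", [1.5, 1.5, 1.5], molecule_id=1)],
    lattice=Lattice(np.eye(3) * 3.0),
    periodic=True,
)
spring = BornSpringModel(cell, cutoff=2.8, k_l=60.0, k_t=15.0)

# destabilise the softest optical mode with a quartic double well
fc0 = phonons.finite_displacement_force_constants(cell, (1, 1, 1), spring.forces)
modes = phonons.modes_at(fc0, (0.0, 0.0, 0.0))
band = 3
pattern = modes.eigenvectors[:, band].real.reshape(-1, 3) / np.sqrt(cell.masses)[:, None]
lam = (modes.frequencies[band] / SQRT_EV_TO_CM1) ** 2 * cell.masses[0]
model = DoubleWellModel(spring, pattern, a=(1.8 * lam - lam) / (4 * 0.09), b=0.9 * lam)

fc = phonons.finite_displacement_force_constants(cell, (1, 1, 1), model.forces)
soft = phonons.modes_at(fc, (0.0, 0.0, 0.0)).frequencies[0]
print(f"softest mode at Gamma: {soft:.1f} cm^-1 (negative = imaginary -> unstable)")

grid = np.linspace(-1.8, 1.8, 41)
mm = map_mode(cell, fc, ((0.0, 0.0, 0.0), 0), grid, model.energy, (1, 1, 1))
i_min = int(np.argmin(mm.energies))
print(f"double well: minimum {mm.energies[i_min]:.3f} kJ/mol at Q = "
      f"{mm.amplitudes[i_min]:.2f} amu^1/2 Å (saddle at Q = 0 by construction)")

relaxed, report = locate_and_reoptimize(mm, cell, (1, 1, 1), model.energy, model.forces)
print(f"re-optimised structure: energy drop {report['energy_drop']:.3f} kJ/mol, "
      f"{report['imaginary_modes_remaining']} imaginary modes remaining")
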