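# crystalgp

Gaussian-process force fields and quasi-harmonic lattice dynamics for
molecular crystals.

Ranking crystal polymorphs needs energies far beyond lattice-energy
arithmetic: thermal and zero-point contributions of a few kJ/mol routinely
reorder phases, and resolving them with periodic electronic-structure
calculations is expensive. `crystalgp` targets that gap for researchers who
want a transparent, fully inspectable implementation of the machine-learned
force-field + lattice-dynamics route: train Gaussian-process models of
per-atom energies and multipole moments on labelled monomer geometries,
assemble a crystal potential, relax, compute phonons, and integrate up to
Gibbs free energies and temperature–pressure phase boundaries. A synthetic
analytic labelling pipeline stands in for the upstream quantum-chemistry
codes, so the whole chain runs on a laptop and every stage is testable
against closed-form oracles.

## The model

**Features.** Each atom A owns an atomic local frame built from two bonded
reference atoms; molecules are described by 3N−6 invariant features (two
reference distances, the enclosed angle, then spherical coordinates of the
remaining atoms).

**Regression.** Per atom and per property, a GP with the product kernel

    k(x, x') = ∏_d exp(−θ_d Δ_d²),

where Δ_d wraps into (−π, π] for angular features. Predictions are
ŷ(x) = μ + Σ_j α_j k(x_j, x) with (K + σ²I)α = y − μ; hyperparameters θ
minimise the RMSE over a held-out validation set.

**Crystal energy.** E = E_intra + E_elec + E_LJ: predicted atomic energies
summed per molecule; point-multipole electrostatics (charge → quadrupole,
moments rotated from each atom's local frame every step) summed in real
space over molecule pairs with a smooth taper; and 12-6 Lennard-Jones,
4ε[(σ/r)¹² − (σ/r)⁶], between molecules.

**Lattice dynamics.** Force constants Φ from ±5·10⁻³ Å single-atom
displacements (6N supercell force calls), acoustic sum rule enforced;
the dynamical matrix D(q) = (m_k m_k′)^(−1/2) Σ_l′ Φ e^{iq·Δr} yields
frequencies ω_j(q), the Helmholtz energy
F = Σ_q,j w_q [ħω/2 + k_BT ln(1 − e^{−ħω/k_BT})], and the quasi-harmonic
Gibbs energy G(T, p) = min_V [F(V; T) + pV] via per-temperature third-order
Birch–Murnaghan fits. Imaginary modes can be mode-mapped: scanning E(Q)
along the unstable eigenvector exposes the double well and the relaxed
distortion is re-screened for stability.

## Worked example

`examples/` holds one short script per capability. Featurisation
(`01_featurize_water.py`):

```
atom 0 (O): A_x=1 A_xy=2 features=[0.9572 0.9572 1.8242]
feature drift under a rigid motion: 4.44e-16  (rotation/translation invariant)
```

— the oxygen's features are its two O–H bond lengths (Å) and the H–O–H angle
(rad), unchanged by rotating the molecule. Relaxing a perturbed toy crystal
(`03_crystal_energy_and_relax.py`):

```
perturbed crystal:  E_intra=-992.498  E_elec=-85.195  E_LJ=-10.508  E_total=-1088.202 kJ/mol per cell
converged: True after 350 steps
cell: a=3.061 b=3.093 c=4.816 Å   alpha=90.00 beta=90.00 gamma=95.17 deg
relaxed energy -1091.786 kJ/mol, residual max force 0.044 kJ/mol/Å
```

— the staged optimizer recovers the known triclinic minimum and its energy
breakdown. Mode mapping (`06_mode_mapping.py`):

```
softest mode at Gamma: -300.2 cm^-1 (negative = imaginary -> unstable)
double well: minimum -8.586 kJ/mol at Q = -1.08 amu^1/2 Å (saddle at Q = 0 by construction)
re-optimised structure: energy drop -8.640 kJ/mol, 0 imaginary modes remaining
```

— the engineered instability maps to a double well and re-relaxes into a
dynamically stable structure 8.6 kJ/mol lower. The other scripts cover GP
training with S-curve diagnostics, phonon dispersion/DoS/Helmholtz curves,
Gibbs surfaces with a pressure-induced phase boundary, and the full
end-to-end pipeline.

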