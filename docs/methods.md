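# Methods

`crystalgp` implements the full chain from geometry-labelled molecular
training data to temperature–pressure phase diagrams of molecular crystals:
Gaussian-process (GP) models of per-atom energies and multipole moments, a
composite crystal potential, staged zero-Kelvin relaxation, finite-displacement
harmonic phonons, and quasi-harmonic Gibbs free energies. This note records
the models, the numerical choices, and what the synthetic test system does and
does not establish.

## Atomic local frames and features

Every modelled atom is the origin of its own right-handed frame: the x axis
points at the highest-priority bonded atom (A_x), the xy-plane is fixed by a
second reference atom (A_xy), and z completes the system. Priority is
(atomic number, atomic mass, original index) descending — a deterministic
stand-in for full Cahn–Ingold–Prelog ordering that coincides with it for the
small molecules targeted here. Terminal atoms take their single neighbour as
A_x and A_x's highest-priority other neighbour as A_xy.

The feature vector of an N-atom molecule has length 3N−6: the two reference
distances and the enclosed angle, then (r, θ, φ) of each remaining atom in
ascending index order. θ is the polar angle measured from the local x axis and
φ the azimuth about it, `atan2(z, y) ∈ (−π, π]`. This assignment is not
arbitrary: a mirror image of a chiral arrangement must flip *only* the
handedness-carrying coordinate, and with φ defined about the A_x bond the
reflection flips φ alone while r and θ are invariant. Features are exactly
invariant under rigid motions (checked to 1e-10 across random SO(3) elements).

## Gaussian-process regression

The covariance is a product Gaussian kernel with one inverse-squared length
scale θ_d per feature; differences of every third feature (the angular ones)
are wrapped into (−π, π] before squaring ("RBF-cyclic"). Outputs are centred
on their arithmetic mean, never variance-scaled; the prediction is
μ + Σ_j α_j k(x_j, x) with α solving (K + σ²I)α = y − μ by Cholesky
factorisation. Diagonal noise σ² is restricted to [1e-14, 1e-6].

Hyperparameters minimise the root-mean-square prediction error over a held-out
internal validation set. The search is a seeded bounded derivative-free
procedure: the all-ones point plus 20 log-uniform draws, refined by
Nelder–Mead in log space; the returned point is never worse than any
candidate, which makes the contract ("no worse than unit length-scales or the
random draws") hold by construction. Noise can optionally join the search
under a flag; by default it is held fixed, and the mean μ is recomputed on
whatever dataset reaches the fit (i.e. after any filtering).

Dataset curation follows the standard campaign shape: a *recovery filter*
drops geometries whose molecular reference energy differs from the sum of
their per-atom labels by strictly more than a threshold (default 1 kJ/mol;
the boundary value is retained), and a *stratified split* bins the output by
the Freedman–Diaconis rule (width 2·IQR·n^{−1/3}), allocating each requested
subset across bins by largest-remainder rounding, disjointly and
reproducibly under one seed. Ties in the remainder go to the lowest bin
index. Model quality is reported as S-curves: sorted absolute errors versus
percentile (100·i/n) over an external set.

Duplicated training inputs with conflicting outputs raise by default; an
explicit flag averages them instead.

## Composite crystal potential

E = E_intra + E_elec + E_LJ.

* **E_intra** — the sum of predicted per-atom energies, molecule by molecule,
  from each molecule's own features. Everything inside a molecule lives here;
  intramolecular LJ and electrostatics are excluded entirely.
* **E_elec** — point multipoles (charge, dipole, quadrupole; rank
  configurable, implemented and validated through quadrupole) in the
  Buckingham convention, predicted in each atom's local frame and rotated to
  the global frame at every evaluation. Interaction tensors are the Cartesian
  derivatives of 1/r through rank four; the implementation is validated
  against point-charge-cluster oracles, whose expansion must converge rank by
  rank.
* **E_LJ** — 12-6 pairs per element pair, 4ε[(σ/r)¹² − (σ/r)⁶]; pairs missing
  from the table simply do not interact.

**Summation scheme.** Sums run in real space over periodic images with a
quintic-smoothstep taper (C² continuous) at the cutoff. The electrostatic
cutoff acts on *molecule pairs* — a pair enters when the two molecule centres
are within the cutoff, and its whole atom–atom block is tapered by the centre
separation. Cutting on neutral molecular units keeps the truncated tail
dipolar (∝ r⁻³); atom-based truncation of charge–charge terms was measured to
produce O(100 kJ/mol) shell artifacts on the test crystal and is not offered.
LJ keeps a plain atom-pair taper. The production default cutoff is 12 Å with
a 2 Å switching window; the desk-scale fixtures use 5 Å matched to their cell
sizes. Periodic systems with a net cell charge are rejected (conditional
convergence); because regression models leave a small spurious net charge on
each molecule (~1e-7 e), the predicted charges are neutralised per molecule
by an equal per-atom shift (on by default).

**Forces.** F = −∂E/∂r with three ingredients: (i) intramolecular — the
analytic kernel gradient chained through the feature Jacobian (closed-form
for the distance/angle core, central differences for spherical-tail features
of larger molecules); (ii) LJ — analytic including the taper derivative;
(iii) electrostatics — central differences on the pair *vector* (exactly
antisymmetric, so Newton's third law and momentum conservation hold to
machine precision) plus the taper-centre term, plus the moment-geometry
coupling: E_elec is bilinear in the site moments, so ∂E/∂(q, μ, Θ) is
assembled analytically in one pass and only the moment prediction itself is
differentiated by finite differences of each molecule's nine coordinates.
The binding contract is agreement with central finite differences of the
total energy (step 1e-5 Å) to 1e-4 kJ/mol/Å, which the suite checks for all
ranks.

## Zero-Kelvin relaxation

Atoms follow their forces by quenched dynamics: the per-atom velocity
accumulates along the force, is zeroed whenever an atom moves against its
force, and is capped at the speed the atom would have at 10 K,
√(3k_B·T/m) — the per-atom interpretation of a thermal speed limit. A step
that would raise the energy is halved (and the velocities reset) until it
descends, so accepted energies are monotone non-increasing and the procedure
is deterministic. Pure velocity-free steepest descent was measured to need
~10⁵ steps on soft lattice modes at a 1 fs pseudo-timestep; the velocity
memory restores the expected convergence without changing the reachable
minimum.

Cell degrees of freedom are released in nested stages — atoms only, then
+cell lengths, then +angles — with the cell moved by steepest descent on the
enthalpy E + pV using central finite differences of the lattice parameters
(relative step 1e-5; atoms ride affinely at fixed fractional coordinates).
The cell step size adapts (×1.25 on acceptance, ×0.5 on rejection). Stage
defaults are 7000 steps, 1 fs, 1 atm.

Convergence requires five gauges *simultaneously, on the same step, in the
final stage*: max force < 2.2 and RMS force < 1.5 kJ/mol/Å, max and RMS step
displacement < 1.8e-3 and 1.2e-3 Å, and per-molecule energy change
< 2e-5 kJ/mol — all strict. Earlier stages that meet the gauges just hand
over to the next stage. These defaults are optimisation-grade only: phonon
work needs residual forces far below them, so the fixture pipelines tighten
all five by roughly two orders of magnitude. A constrained-volume variant
rescales isotropically to the target and renormalises every cell update back
onto the constant-volume manifold (|V − V_target|/V_target < 1e-8).

## Harmonic phonons

Force constants come from central differences of forces under single-atom
displacements of ±5e-3 Å along x, y, z — exactly 6N displaced supercells for
an N-atom cell, no symmetry reduction. The cell handed in may be a primitive
cell extracted from a relaxed supercell, which divides the displacement count
by the supercell factor (216 instead of 13824 for a 36-atom cell under a
4×4×4 expansion). Pair blocks are symmetrised (Φ(0k, l′k′) against
Φ(0k′, −l′k)ᵀ), then the self-terms absorb the row sums (acoustic sum rule),
pinning three zero modes at Γ.

The dynamical matrix is the mass-weighted Bloch sum with atomic-position
phases. Supercell-folded image offsets are unwrapped to their shortest
translates (ties share the weight) before the Fourier sum — without this
minimum-image step, interpolation between commensurate wavevectors is wrong
even for short-ranged models. Frequencies are sign(λ)√|λ| converted to cm⁻¹
(negative = imaginary, the plotting convention); eigenvectors are the
orthonormal mass-weighted columns. **The FD supercell must contain the
interaction range**: half the smallest supercell dimension below the cutoff
aliases the force constants, and on the toy crystal this manifested as a
spurious −148 cm⁻¹ mode at an incommensurate wavevector that a proper 3×3×2
supercell shows to be +72 cm⁻¹.

DoS is a Gaussian-broadened histogram over a regular Γ-centred mesh (16³
production default, uniform weights, no symmetry folding); its integral is
3N_b to quadrature accuracy. The Helmholtz free energy per cell is
Σ w_q [ħω/2 + k_B·T ln(1 − e^{−ħω/k_BT})], with U and S evaluated
independently and F = U − TS holding to 1e-10. The three Γ acoustic modes are
dropped from thermodynamics; any frequency below −0.1 cm⁻¹ aborts with a
count (never silently skipped), and small negatives within that tolerance are
clamped to it as numerical-noise floor, with the clamp count reported.

Unit chain: kJ/mol, Å, amu, fs internally; CODATA 2018 constants live in one
module, including the Coulomb prefactor 1389.35457644382 kJ·Å/(mol·e²) and
the conversion √(kJ/mol/Å²/amu) → 53.088 cm⁻¹.

## Quasi-harmonic free energies

A relaxed structure is constrained-relaxed at a bracket of volumes (default
seven over ±5%; asymmetric windows supported), each volume gets a harmonic
F_vib(T), and F(V; T) = E_static(V) + F_vib(V, T) is fitted per temperature
to the third-order Birch–Murnaghan form. Volumes that turn out dynamically
unstable are excluded with a log entry; fewer than four usable volumes aborts
the fit. Initial guesses come from a parabola through the three lowest-F
points (V₀ at the vertex, B₀ from the curvature, B₀′ = 4); the least-squares
refinement is bounded (V₀, B₀ > 0) so the ⅔-powers stay real.

G(T, p) = min_V [F(V; T) + pV] is solved by root-finding p(V) = −dF/dV on the
analytic derivative of the fit; minimising volumes outside 1.5× the scanned
range raise an extrapolation error. Pressures are GPa at the interface
(1 GPa = 0.602214 kJ/mol/Å³). Phase ranking is per molecule (cells differ in
molecule count); crossing temperatures interpolate between strictly-signed
grid stretches, so identically-degenerate curves report none. Phase
boundaries p*(T) come from bisection on ΔG(p) to 1e-4 GPa; temperatures
without a strict sign change in the window are omitted and logged — which is
also how metastable phases (never lowest G anywhere) surface rather than
disappear. Fits are per-temperature, independent; no smoothing across T.

## Mode mapping

An imaginary mode's eigenvector defines a distortion pattern
u_{lk} = Q·W_k·Re[e^{2πiq·(l+τ)}]/√(m_k N), normalised so
Σ m u² = Q² — Q is the mass-weighted normal-mode amplitude, hence the mapped
curvature at Q = 0 equals the mode's ω² directly (checked to 5%). Wavevectors
must be commensurate with the supercell (the error names the minimal
commensurate expansion); ±q pairs combine as the real cosine with the phase
fixed by the first atom's largest eigenvector component. E(Q) − E(0) is
evaluated on the commensurate supercell; a genuine instability yields a
double well, whose minimising distortion is relaxed and re-screened for
imaginary modes.

## The synthetic data generator

The quantum-chemistry labelling pipeline is replaced by an analytic
water-like monomer surface: a positive-definite quadratic form in
(Δr₁, Δr₂, Δθ) with stretch–stretch and stretch–bend couplings
(k_r = 4600 kJ/mol/Å², k_θ = 320 kJ/mol/rad², k_rr = −100, k_rθ = 90,
r₀ = 0.9572 Å, θ₀ = 104.52°), chosen so the monomer's bend lands near
1600 cm⁻¹ and the stretches near 3700 cm⁻¹ — water-like, making unit errors
conspicuous. Per-atom energies are static shares (O ½, H ¼ each) of the
molecular energy plus a smooth redistribution term that sums identically to
zero, so the "recovery error" of clean data is exactly zero — the partition
makes no claim to the physics of a real energy decomposition, only to its
data shape. Charges respond linearly to the internal displacements and sum
to zero; the oxygen carries a small local-frame dipole and a constant
traceless quadrupole. An `AnalyticIntraModel` inverts each atom's features
back to the molecule's internal coordinates (law of cosines on the feature
triangle) and reproduces the labels exactly without regression — the
training-free oracle the energy machinery is tested against.

Geometry sampling is seeded Gaussian in the internal coordinates
(σ_r = 0.05 Å, σ_θ = 0.12 rad by default, spanning ≥100 kJ/mol over a few
thousand draws — a high-temperature-like width); non-physical draws are
resampled and counted, and every geometry gets a random rigid pose so
invariance is genuinely exercised downstream.

The toy crystal places two inversion-related monomers (zero cell dipole) in
a cell with fixture LJ parameters (O–O 0.80/3.00, O–H 0.30/2.30, H–H
0.15/1.80 kJ/mol / Å) and rank-1 electrostatics at a 5 Å molecule-pair
cutoff. Its relaxed reference (triclinic, γ ≈ 95°) is stored in the package:
reaching it from the ideal-sites start takes a long staged relaxation, and
dynamical stability was verified on a 3×3×2 mesh with an alias-free 3×3×2 FD
supercell. The end-to-end pipeline (sample 2000 → filter → 200/100/1000
split → train 15 per-atom GP models → staged relax → phonons → seven-volume
quasi-harmonic scan) starts from that reference and completes in a few
minutes on one CPU; the problem sizes (2-molecule cell, 3×3×2 supercell and
mesh) are the package's chosen desk-scale study conditions. The toy crystal
destabilises under a few percent of compression — a pressure-induced soft
mode lives just below the equilibrium volume — so the quasi-harmonic window
is asymmetric (−1.5% to +7.5%) and the temperature grid runs 10–100 K; above
that the F(V) minimum migrates into the stability edge and the volume
bracket no longer contains it. Constrained-volume scans relax atoms at the
isotropically scaled cell shape: releasing the shape at fixed volume proved
path-dependent between near-degenerate shape minima and made F(V) rough at
the 1 kJ/mol level.

**What the fixtures do not show.** The synthetic surface is exactly
harmonic-with-couplings and its labels are noise-free; real labelled data
carry integration noise, recovery errors, and anharmonicity, so passing
these tests demonstrates the machinery (featurisation, regression,
summation, lattice dynamics, thermodynamics) — not transferability of any
trained model to real crystals. Intermolecular polarisation is absent by
construction (monomer-only models), and the LJ table is a fixture choice,
not a fitted force field.

## Known limitations

* Electrostatics is real-space tapered, not Ewald-summed; adequate for
  neutral molecular systems at desk scale, unsuitable for ionic crystals.
* Interaction tensors stop at quadrupole–quadrupole (the rank interface
  accepts 0–2).
* No symmetry anywhere: relaxation does not preserve space groups, phonon
  meshes are not symmetry-folded, and displacement sets are not reduced.
* The harmonic free energy has no LO–TO correction and no anharmonic terms
  beyond the quasi-harmonic volume dependence.
* `relax` is a local optimiser; it finds the nearest basin of the staged
  descent path, not the global packing.
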