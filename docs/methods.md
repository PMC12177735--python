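# Methods

This document records the modeling assumptions, numerical choices, and
known limitations of the `photohop` package. Everything stated here is a
property of the implementation; quantitative results (time constants,
yields, error measures) are produced by the code itself — see the test
suite and `scripts/acceptance.py` — and are not asserted in prose.

## 1. Scope and design

The package simulates nonadiabatic photodynamics of a
carbonyl-functionalized bicyclic ring-opening reaction at toy scale:
a photoexcited reactant relaxes from S1 by intersystem crossing to T1
(and, less importantly, T2) and opens two C–C bonds in sequence to reach
the ring-opened product. All electronic structure comes from analytic
"oracle" models, so every quantity a real ab initio workflow would
compute (energies, gradients, spin–orbit coupling norms) is available
exactly, cheaply, and differentiably. The machine-learning surrogate,
the surface-hopping engine, and the ensemble analysis are the objects of
study; the oracle is the ground truth they are measured against.

## 2. Model systems

### 2.1 Four-atom ladder model (`ladder`)

The main model is a 4-atom C–C–C=O chain whose diabatic energies depend
only on interatomic distances, so the model is exactly invariant to
rigid rotations and translations. Three distances have chemical roles:

- `R1` (atoms 0–1): the carbonyl-side breakable ring bond,
- `R2` (atoms 1–2): the unsubstituted-ring breakable bond,
- `R3` (atoms 2–3): the carbonyl C=O stretch, which tunes the
  spin–orbit coupling and the singlet–singlet gap.

Four electronic states are carried: S0, S1 (singlets) and T1, T2
(triplets). Per spin manifold, diabatic potentials (Morse-like
closed/open wells in `R1` and `R2`, harmonic `R3` terms, scaffold
restraints, short-range repulsion, quartic confinement) are assembled
and the 2×2 manifold Hamiltonian is diagonalized analytically;
gradients follow from the Hellmann–Feynman theorem, so adiabatic
energies and gradients are mutually consistent to machine precision.
Singlet–triplet SOC norms are sigmoidal functions of `R3` (larger for a
stretched carbonyl), in cm⁻¹.

The parameters (`_default_ladder_params`) are calibrated so that:

- vertical Franck–Condon gaps are S1 = 3.60 eV, T1 = 3.40 eV,
  T2 = 3.55 eV (`gap_s1/gap_t1/gap_t2` are enforced by a constant
  per-state shift at the reference geometry);
- ring opening is stepwise and exothermic, with the carbonyl-side bond
  `R1` opening before `R2` (the `bond_asym` multipliers deepen the
  closed well of `R2` on the excited states);
- S1 and T1 cross along the opening coordinate, with SOC norms of order
  10–300 cm⁻¹ controlled by the carbonyl stretch.

All model parameters can be overridden from the run configuration
(`model.parameters` is an open config block).

### 2.2 One-dimensional fixtures

Four single-coordinate models (`avoided_crossing`, `dual_crossing`,
`singlet_triplet`, `harmonic_2state`) provide closed-form test beds for
the propagators and hopping logic. They are used by the test suite and
are available from the CLI for experimentation.

## 3. Initial conditions

Harmonic normal modes are obtained at the S0 minimum by finite-difference
Hessian (`normal_modes`), with translation/rotation projected out.
Initial conditions are drawn from the ground-state harmonic Wigner
distribution: each mode's mass-weighted coordinate and momentum are
independent Gaussians with Var(Q) = ħ/(2ω) and Var(P) = ħω/2. Sampling
removes center-of-mass velocity, and optionally rigid rotation, from the
Cartesian velocities. Trajectories start on S1 (vertical excitation).

## 4. Dynamics

### 4.1 Nuclear propagation

Velocity Verlet with a 0.5 fs default step on the active adiabatic
surface. Total energy is monitored; drift beyond `drift_bound_ev`
(default 0.5 eV) flags or aborts the trajectory per configuration.

### 4.2 Electronic propagation

The electronic wavefunction evolves in the spin-diabatic representation
under the generator K = diag(E) + H_SOC − i·σ (ħ = 1), where σ holds
the antisymmetric scalar time-derivative couplings within each spin
manifold and H_SOC the symmetric singlet–triplet SOC norms. Each nuclear
step is divided into `electronic_substeps` (default 20) substeps, and
each substep applies a fourth-order commutator-free Magnus integrator
(Blanes–Moan CF4): two exact exponentials of Hermitian-combination
generators evaluated at the two Gauss–Legendre nodes of the substep,
with weights (3 ± 2√3)/12. The scheme is exactly norm-conserving (each
factor is a unitary matrix exponential, computed by eigendecomposition),
exact for time-independent generators, and has O(h⁵) local error, so
halving the substep at production settings changes final amplitudes near
round-off. The off-diagonal elements of K are interpolated linearly
between consecutive nuclear steps.

### 4.3 Couplings

Internal conversion uses curvature-driven (Baeck–An) time-derivative
couplings: σ = ½·√(ΔE″/ΔE) from a three-point finite-difference
curvature of the adiabatic gap. The coupling is gated to zero when the
gap is at or above `gap_gate_ev` (default 0.5 eV), when the curvature is
non-positive, and during the first two steps of a trajectory (no gap
history yet). Setting the gate to 0 eV disables internal conversion
entirely; the configuration validator therefore accepts any nonnegative
gate. Intersystem crossing is driven directly by the SOC norms; setting
them to zero disables ISC.

### 4.4 Hopping

Fewest-switches hop probabilities are accumulated per target state as
the trapezoid-rule integral of the per-channel probability flux over the
electronic substeps, normalized by the active-state population at the
start of the nuclear step, and clamped to [0, 1] after negative-flux
removal. A hop is labelled ISC or IC by its dominant channel. Accepted
hops rescale the velocity isotropically (uniform scaling of all
Cartesian velocities) to conserve total energy exactly; energetically
forbidden hops are recorded as frustrated and leave the velocity
unchanged. No decoherence correction is applied.

### 4.5 Trajectory-level reproducibility

Each trajectory draws its hop random numbers from its own
`numpy.random.SeedSequence(base_seed, spawn_key=(index,))` substream,
so ensemble results are a function of the global trajectory index only:
identical across reruns, across trajectory orderings, and across any
partitioning of the ensemble over workers.

## 5. Surrogate model

### 5.1 Descriptor and networks

Geometries are featurized as inverse interatomic distances (rigid-motion
invariant; analytic Jacobian for gradient back-transformation, with a
hard floor that raises on near-coincident atoms). Energies/gradients are
learned by per-state multilayer perceptrons (two hidden layers of 64,
leaky-softplus activations); the training loss combines energy and
gradient errors, with gradients obtained by exact double
backpropagation, so predicted gradients are the exact derivatives of the
predicted energies. SOC norms are learned by a separate softplus-headed
network (nonnegative outputs). Inputs and targets are z-scored on the
training split.

### 5.2 Committee and uncertainty

Two members per quantity are trained from different initializations on
the same 90:10 train/validation split. The committee prediction is the
member mean; the member spread is the uncertainty estimate. A running
trajectory stops with termination `uncertainty-stop` when the spread
exceeds any of the thresholds: 0.05 hartree (energy), 0.25 hartree/bohr
(gradient), 60 cm⁻¹ (SOC norm).

### 5.3 Training data and adaptive sampling

The initial training set is the union (deduplicated) of
- Wigner samples about the Franck–Condon point,
- linear interpolation paths connecting the S0-relaxed basins (closed,
  open-R1, open-R2, product) and carbonyl-stretch legs toward the S1/S0
  funnel in each basin,
- strided snapshots from a small number of short oracle trajectories
  (`training.n_seed_trajectories`), which cover the regions dynamics
  actually visits — interpolation paths alone were found (by the
  package's own diagnostics) to leave trajectory regions uncovered.

The adaptive loop then alternates: train a committee, run
surrogate-driven trajectories with uncertainty monitoring, harvest the
final geometry of every uncertainty-stopped trajectory, label harvested
points with the oracle, discard energy outliers (> 1 hartree above the
dataset floor) and duplicates, and retrain. It stops early when a round
harvests nothing.

## 6. Analysis

- **Geometry classification.** A frame is `closed` (region 1),
  `open-R1` (2), `open-R2` (3), or `product` (4) by comparing `R1` and
  `R2` against a 2.2 Å threshold.
- **Populations.** Classical state populations on a common time grid;
  a trajectory contributes its active state while the grid time does not
  exceed its own final time, and leaves the denominator afterwards, so
  early-stopped trajectories never extrapolate.
- **Kinetics.** The ISC time constant is a least-squares exponential fit
  (linear or log domain) to the donor (singlet) population decay.
- **Quantum yield.** Fraction of trajectories whose final frame is in
  the product region, with pathway classes assigned by the first
  singlet→triplet hop (`via S1->T1`, `via S1->T2`, `remaining-S1`).
  Early-stopped trajectories are excluded from yields and the reaction
  network by default.
- **Hop regions.** Geographic statistics of where a given hop pair
  fires (latest hop per trajectory, or final-snapshot mode).
- **Reaction network.** Directed graph over (region, state) nodes with
  per-trajectory deduplicated edge counts; edge percentages below 1%
  are labelled `0%` but keep their counts.
- **Drift report.** End-of-trajectory and peak |ΔE_total|, and drift
  before the first hop.

## 7. Determinism

All stochastic stages (sampling, training splits and initialization,
adaptive rounds, per-trajectory hopping) derive their seeds from the
single configured master seed through named `SeedSequence` substreams;
derived seeds are reduced modulo 2³¹. No timestamps are written to any
artifact, so a repeated run with the same configuration is byte-identical,
including all CSV/JSON/GML analysis tables.

## 8. Limitations

- Classical nuclei, harmonic Wigner sampling, and no decoherence or
  phase correction in the hopping algorithm: tunneling, zero-point leaks
  and overcoherence artifacts of plain FSSH are all present.
- Velocity rescaling at hops is isotropic rather than along a coupling
  vector (the curvature-driven scheme provides no direction).
- Curvature-driven couplings approximate true derivative couplings and
  switch on only after two steps of gap history; very fast passages
  through crossings can be under-resolved.
- The ladder model's diabatic surfaces depend only on distances and are
  calibrated for qualitative, not quantitative, realism; its S1/S0
  internal-conversion funnel is weakly coupled by construction, so the
  photochemistry is ISC-dominated.
- Committee-of-two spread is a crude uncertainty estimate: both members
  can agree and be wrong, which is why trajectory-seeded initial data
  matter more than additional adaptive rounds.
- Training paths are straight lines in Cartesian space, not geodesic
  or internal-coordinate interpolations.
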