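# photohop

Machine-learning-accelerated nonadiabatic photodynamics on analytic model
surfaces: Wigner sampling, committee neural-network surrogates with
uncertainty-driven adaptive sampling, generalized fewest-switches surface
hopping with intersystem crossing, and trajectory-ensemble mechanism
analysis.

## The science

Photoexcited carbonyl-functionalized bicyclic dienes can open two C–C
ring bonds in sequence to form a cyclooctatetraene-like product. The
mechanistic question is how the molecule leaves the initially excited
singlet: with a carbonyl group present, spin–orbit coupling (SOC) at the
stretched C=O geometry funnels population from S1 into the triplet
manifold (S1 → T1 intersystem crossing), and ring opening proceeds on
the triplet surface, bond by bond.

`photohop` studies this mechanism at toy scale. A four-atom "ladder"
model (C–C–C=O) carries four electronic states (S0, S1, T1, T2) with
analytic energies, gradients and SOC norms, calibrated to vertical
excitation gaps of 3.60 / 3.40 / 3.55 eV (S1 / T1 / T2) and a stepwise,
exothermic two-bond opening in which the carbonyl-side bond breaks
first. Because the oracle is analytic, every component of the ML-driven
workflow — surrogate accuracy, hopping statistics, ensemble analysis —
can be validated against exact ground truth:

- **Initial conditions**: harmonic-Wigner phase-space sampling at the S0
  minimum, vertical excitation to S1.
- **Dynamics**: velocity-Verlet nuclei on the active adiabatic surface;
  electronic amplitudes propagated in the spin-diabatic representation by
  a fourth-order commutator-free Magnus integrator; internal conversion
  via curvature-driven (Baeck–An) time-derivative couplings gated at
  0.5 eV; intersystem crossing via SOC norms; exact energy conservation
  at every hop through isotropic velocity rescaling.
- **Surrogate**: committees of two neural networks per quantity
  (energies+gradients per state, SOC norms) on inverse-distance
  descriptors, with gradient-consistent training (predicted gradients are
  the exact derivatives of predicted energies); committee spread triggers
  trajectory early-stops and adaptive harvesting of new training data.
- **Analysis**: classical state populations, ISC time constants, product
  quantum yields by pathway, hop-region statistics, reaction networks
  over (geometry region, state) nodes, and energy-drift audits.

See `docs/methods.md` for assumptions, parameter choices, and
limitations.

## Worked example

Sample 48 Wigner initial conditions, propagate a surface-hopping
ensemble on the oracle, and analyze the mechanism (everything below is
real output, reproducible byte for byte from these exact commands):

```console
$ photohop sample --set seed=7 --set sampling.n_samples=48 --out ics
wrote 48 initial conditions to ics

$ photohop dynamics --set seed=7 \
    --initial-conditions ics/initial_conditions.npz --out dyn
propagated 48 trajectories (oracle); terminations: {'reached-max-time': 48}

$ photohop analyze --set seed=7 --ensemble dyn/ensemble.npz --out ana
product yield: 22.9% over 48 trajectories
```

`ana/analysis.json` then contains, among other things (400 fs of
dynamics — many triplet trajectories have not finished opening the
second bond yet):

```text
kinetics.tau_fs                  344.6        # S1 decay time constant
yield.n_product                  11 / 48      # 22.9% product within 400 fs
yield.by_pathway                 {"via S1->T1": 10, "via S1->S0": 1}
yield.final_states               {"S0": 8, "S1": 9, "T1": 28, "T2": 3}
hop_regions_S1_T1.n_matching     43           # trajectories with S1->T1 hops
hop_regions_S1_T1.mean_bond_lengths.R3   1.372   # stretched C=O at the hop
drift.mean_end_drift_ev          0.0019       # energy conservation audit
```

and `ana/populations.csv` holds the population table
(`time_fs,count,S0,S1,T1,T2`). A reaction network with per-edge
trajectory counts is written to `ana/network.gml`.

To run the same ensemble on a trained surrogate instead of the oracle:

```bash
photohop adaptive --set seed=7 --out model     # adaptive training loop
photohop dynamics --set seed=7 --set dynamics.provider=surrogate \
    --model-file model/model.npz \
    --initial-conditions ics/initial_conditions.npz --out dyn_surr
```

`photohop config --defaults` prints every configurable knob;
`photohop report` aggregates several analyze outputs. Each stage writes
a `manifest.json` (config echo, derived seeds, input digests); no
artifact contains a timestamp, so identical seeds give byte-identical
outputs across reruns and across any partitioning of trajectories over
workers.

## Reproduction

```bash
# full test suite (unit + property + acceptance; the surrogate-fidelity
# gate trains committees and propagates matched 200-trajectory
# ensembles, which dominates the runtime: ~13 min on one CPU)
python -m pytest -q

# end-to-end acceptance report: runs the whole pipeline at desk scale
# and writes every headline quantity as {"name": {"value": ..., "n": ...}}
python scripts/acceptance.py --seed 1 --out acceptance.json
```

All randomness in the acceptance script derives from `--seed` through
named substreams; a given seed reproduces the report exactly.

## Package layout

```
src/photohop/
  model_systems.py    analytic oracles (4-atom ladder + 1D fixtures),
                      normal modes
  initial_conditions.py  Wigner sampling, training-geometry assembly
  dynamics.py         generalized FSSH engine (VV nuclei, CF4 electronic
                      propagator, kTDC, ISC/IC hops, ensembles)
  surrogate/          descriptor, gradient-consistent MLPs, committees,
                      adaptive sampling
  analysis.py         populations, kinetics, yields, hop regions,
                      reaction networks, drift audits
  cli.py              photohop sample|train|adaptive|dynamics|analyze|report
  xyz.py, archive.py, config.py, geometry.py, constants.py, errors.py
tests/                unit, property (hypothesis) and acceptance tests
scripts/acceptance.py end-to-end acceptance report
docs/methods.md       assumptions, numerical choices, limitations
```
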