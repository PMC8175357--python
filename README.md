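# rigidbd

Rigid-body Brownian-dynamics (BD) association on a membrane, as a
tested, reusable Python library: grid-map force fields, Boltzmann-
inverted membrane restraints, an overdamped rigid-body propagator,
pose clustering and scoring, phosphomimetic rescoring, and the channel
analyses (ion-crossing currents, pore-radius profiles, hydrogen bonds)
that complete the workflow.

## The problem

How does a peripheral, membrane-anchored protein find its binding site
on a membrane channel?  Atomistic simulation of the diffusional search
is hopeless at scale, so the established strategy is hybrid: keep both
proteins rigid, replace the stationary protein by precomputed potential
maps on a regular grid, keep the mobile protein anchored at its
membrane insertion depth by statistical restraints, and let overdamped
Brownian dynamics with thermal noise explore the two-dimensional search
space for microseconds per replica.  The trajectories are then reduced
to contact frames, RMSD pose clusters, anchor hot-spot densities and
interaction energies; in-silico charge perturbations (e.g. placing a
phosphoserine at a rim residue) rescore the discovered poses, and
channel-permeation analyses quantify what a bound partner does to ion
conduction.

`rigidbd` implements that entire protocol for anyone studying
protein–protein association at a membrane — with first-class synthetic
study systems so every stage is verifiable against known ground truth
without any external data.

## The model in brief

The mobile body carries charge and Lennard-Jones particle densities
ρ(cell) deposited on a 1 Å body-frame grid; the stationary body is an
electrostatic potential map V_elec plus one LJ map per collapsed atom
category ({H}, {O,N}, {C,S}, well depths scaled by 0.3).  At pose
(x, q) each occupied cell feels f = −ρ ∇V at its transformed centre;
forces and torques are summed and the pose advances by the overdamped
update

    Δx = (D_t/k_BT) F Δt + √(2 D_t Δt) ξ,
    Δφ = (D_r/k_BT) τ Δt + √(2 D_r Δt) ξ_rot,

with Δφ applied as a quaternion exponential.  Membrane anchoring uses
per-residue potentials U(z) = −k_BT ln p̂(z) inverted from z-coordinate
samples; a circular harmonic wall bounds the lateral search.  Crossing
counts obey a strict below→inside→above state machine and currents
follow I = N·q/τ; pore profiles report the largest clash-free probe
sphere per slice.  `docs/methods.md` has the full account.

## Worked example

Five replicas of a charged anchored probe searching a barrel with a
charged rim patch (`examples/03_run_association.py`):

```python
from rigidbd import run_pipeline

manifest = run_pipeline({
    "seed": 7,
    "outdir": "scratch/example_association",
    "replicas": 5,
    "duration_ns": 30.0,
})
```

prints

```
frames: 755, in contact: 666
cluster 0: population 0.98, representative energy elec -73.6 vdw -0.6 kcal/mol
cluster 1: population 0.02, representative energy elec -66.3 vdw +0.2 kcal/mol
anchor hot spot at (18.0, 0.2) A -> azimuth 0 deg (patch sits at 0 deg)
rescoring (original/perturbed electrostatics) per cluster: {'0': 1.33, '1': 1.36, ...}
```

Read: 88% of saved frames are in atomic contact (≤3 Å) with the
barrel; almost all contact poses fall in one RMSD cluster whose best
member binds at −74 kcal/mol electrostatic energy; the anchor's
occupancy density peaks at the rim patch azimuth; and adding −2 e at
the rim "site" residue weakens the bound-state electrostatics 1.3-fold
— the pose search found the charged patch and the rescoring responds
to the perturbation, exactly as designed.

The other examples each exercise one capability: force-field
construction (`01`), restraint derivation (`02`), ion currents (`04`,
including exact recovery of a scheduled crossing count), and pore
profiling with a partial mouth blockade (`05`).

A thin CLI mirrors the stages for shell use:

```bash
rigidbd simulate-toy --out-prefix toy
rigidbd make-maps toy_barrel.pqr --out-prefix maps
rigidbd pore toy_barrel.pqr --z-step 1
rigidbd pipeline config.yaml
```

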