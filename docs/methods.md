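# Methods

## Scope and model

`rigidbd` implements a hybrid protocol for finding membrane-protein
binding poses by rigid-body Brownian dynamics (BD), together with the
trajectory analyses that turn such simulations into results: pose
clusters, hot-spot densities, interaction energies, charge-perturbation
rescoring, ion-crossing currents and pore-radius profiles.  The
motivating system is a mobile, membrane-anchored enzyme fragment
searching the rim of a stationary β-barrel channel in the outer
mitochondrial membrane, but every component is generic.

Both bodies are rigid.  The stationary body is represented by scalar
potential maps on a regular grid: one electrostatic map (kcal/(mol·e))
and one Lennard-Jones map per collapsed atom category (kcal/mol).  The
mobile body is represented by density grids in its own frame: charge
per cell and LJ-particle count per cell and category, deposited once by
trilinear (cloud-in-cell) weighting and rigidly transformed every step
— there is no re-deposition during a run.  Each occupied density cell
feels the local force −ρ ∇V of its matching map (charge ↔ electrostatic
map, category count ↔ that category's LJ map, no cross terms); cell
forces and their torques about the centre of mass are summed.

### Units

Lengths Å, energies kcal/mol, time ns, charges e, temperature K.
k_B = 0.0019872 kcal/(mol·K); Coulomb constant 332.0636 kcal·Å/(mol·e²).

## Force-field construction

**LJ category collapsing.**  The stationary body's atoms are grouped
into three element classes — all hydrogens; oxygen + nitrogen; carbon +
sulfur — each carrying the arithmetic mean of the member atoms' Rmin
and of their well-depth magnitudes.  The mean well depth is multiplied
by 0.3 by default, a softening that prevents rigid bodies from
sticking irreversibly (internal relaxation, which would relieve
over-close contacts in a flexible model, is absent here).  LJ maps use
Lorentz–Berthelot combination of the category parameters against each
stationary atom's own parameters and are clamped from above at
30 kcal/mol so nodes inside atoms stay finite.

**Electrostatics.**  Production-grade electrostatic maps belong to a
Poisson–Boltzmann solver; the package imports any such map through
OpenDX files and records the provenance.  The built-in alternative is a
uniform-dielectric Debye–Hückel map, V(r) = 332.0636 Σ q_i
exp(−d_i/λ_D)/(ε_s d_i), with λ_D = 3.04/√I Å (I in molar; the 298 K
water constant — the temperature correction is negligible at this
fidelity).  Values are clamped to ±cap (default 30) so cells at atom
centres stay finite.  It carries no dielectric boundary, so fields
inside a low-dielectric protein core are overscreened relative to a PB
solution; for the validation toys, whose charges sit on the surface,
this is immaterial.

**Interpolation.**  Forces use the analytic gradient of the trilinear
interpolant (piecewise multilinear per cell).  This makes the grid
force exactly the negative gradient of the interpolated pose energy —
verified by finite differences in the tests — at the cost of a gradient
that is discontinuous across cell faces.  The measured force error
against a direct pairwise oracle on 20-bead bodies is ~3–5% at 1 Å
spacing and decreases monotonically with refinement (≈2.5% at 0.5 Å,
≈1.3% at 0.25 Å).

**Cutoff.**  The production protocol's 34 Å interaction cutoff is
realised at map-construction time (map contributions vanish beyond the
cutoff distance from each source atom), not by per-step distance tests.

## Membrane restraints

The membrane is implicit.  Anchoring enters through one-dimensional
potentials U(z) = −k_B T ln p̂(z) obtained by Boltzmann inversion of
the z-coordinate samples of four named anchor residues, estimated by a
histogram (default bin 0.5 Å) with a pseudocount of 1 in empty interior
bins, shifted so min U = 0.  Outside the sampled support U continues
with the linear slope of its edge — the anchor stays confined without
infinite walls, and the behaviour is defined everywhere.  The restraint
force acts on the world z of each anchor point (rigidly transformed
from the body frame) and contributes torque through its lever arm about
the COM, exactly like a grid force.  A histogram rather than a kernel
estimator keeps the inversion deterministic and directly testable.

Lateral confinement is a circular harmonic wall on the COM: zero force
inside the wall radius (production default 150 Å; 60 Å in the scaled
toy), inward force k(r − R) beyond it, k = 10 kcal/mol/Å² by default
(the production protocol specifies only the radius; the stiffness is
configurable and only needs to be large enough to make excursions
rare).  Frames are aligned by shifting the mobile body so both
membrane midplanes coincide.

## Propagation

The propagator is the first-order overdamped (Ermak–McCammon) update

    Δx = (D_t/k_BT) F Δt + √(2 D_t Δt) ξ
    Δφ = (D_r/k_BT) τ Δt + √(2 D_r Δt) ξ_rot

with independent standard-normal noise per axis; Δφ is applied as an
exponential-map quaternion increment with per-step renormalisation.
At a 200 fs step and protein-scale friction, momentum relaxes far
below one step, so the inertialess limit is the appropriate reading of
a Langevin thermostat for this system.  Diffusion is isotropic
(scalar D_t, D_r): pose discovery does not depend on the detailed
diffusion tensor, and a Stokes–Einstein helper converts a hydrodynamic
radius to coefficients when bead-model values are not supplied.

The Euler discretisation biases the sampled variance of a harmonic
well by a factor 1/(1 − θΔt/2), θ = D k/k_BT; keeping θΔt ≲ 0.05
(e.g. 250 fs at D_t = 100 Å²/ns in a 0.6 kcal/mol/Å² well) holds the
bias near 1%.  The engine warns when a step displacement exceeds two
grid cells.

All replicas advance together through one vectorised loop; each
replica draws from its own generator spawned from the run seed, so
runs are bit-reproducible, replicas are independent, and results do
not depend on the number of replicas run together.

## Trajectory analysis

* **Contacts** — a frame is in contact when any inter-body atom pair is
  within 3.0 Å (k-d-tree implementation, equal to the brute-force
  double loop by construction and by test).
* **Clustering** — greedy quality-threshold clustering on pairwise RMSD
  (default cutoff 10 Å) of the mobile body's reference atoms expressed
  in the stationary frame with no refitting: the frame with the most
  neighbours seeds each cluster, ties break on the lowest index, so the
  result is deterministic and permutation-stable up to seed identity.
* **Representatives** — the member frame with the lowest (most
  favourable) electrostatic + vdW pairwise interaction energy; energies
  use a hard 12 Å cutoff and no switching function.
* **Hot spots** — Gaussian KDE (Scott's rule by default) of the anchor
  COM over the membrane plane on a 1 Å grid, renormalised to integrate
  to exactly 1.
* **Phosphomimetic rescoring** — per cluster, the mean electrostatic
  energy is recomputed with one stationary residue's charges replaced
  (e.g. a phosphoserine charge set) and the original/modified ratio is
  reported; an identity replacement gives exactly 1.
* **Geometry** — tilt angle of a body axis against the membrane normal;
  per-residue insertion depth as COM z relative to the phosphate plane
  (negative = deeper), mean ± sd over frames.

## Channel analyses

**Crossing counting** is a three-state machine (below/inside/above the
slab): a crossing is counted only on below→inside→above or the
reverse.  Entries that retreat to the same side count nothing, and so
does a discrete jump straight across the slab with no sample inside it
— the slab faces are the only thresholds, with no hysteresis buffer, so
the definition is exactly testable.  Currents follow I = Σ_s net_N_s
q_s/τ with q = ±1.60217662×10⁻¹⁹ C and upward crossings positive.

**Pore profiles** report, per z-slice, the largest sphere centred in
that plane that touches no atom's vdW sphere (full 3-D distances).  The
centre is optimised by a coarse 0.5 Å grid search in a window around
the previous slice's centre (so the centre line tracks curved pores)
followed by Nelder–Mead refinement — a deterministic replacement for
Monte-Carlo search tools.  Radii clamp at 15 Å where the pore opens to
bulk, with a flag.

**Hydrogen bonds** use the geometric criterion D–A < 3 Å and
D–H–A > 120° (angle at H); donors without a bound hydrogen are skipped
with a warning.

## Synthetic study system

The generators emulate the statistical structure of the real inputs at
a scale where every claim is testable in seconds-to-minutes on one CPU:

* a **barrel** of beads on a cylindrical lattice (radius 15 Å, height
  35 Å, 12 rings × 36 — denser than one bead diameter so the probe
  cannot slip through the wall), whose top "rim" ring carries a charged
  patch (default +10 e shared over a 50° arc) and a single-atom mutable
  "site" residue for rescoring studies;
* an **anchor probe** of 20 beads on a helix with four labelled anchor
  residues (positions 1, 10, 15, 20); its charge (default −8 e) lives
  on the middle bead segment, emulating a charged interaction segment
  on an otherwise hydrophobic anchor.  Bead Rmin/2 is 1.3 Å, placing
  the LJ pair minimum at 2.6 Å — inside the 3 Å contact cutoff, so
  bound poses register as atomic contacts;
* Gaussian **z-samples** of an anchored residue (variance k_BT/k);
* **ion tracks** realising an exact schedule of complete crossings,
  feints and direction-resetting jumps, with clipped Gaussian noise
  that provably cannot alter the scheduled counts;
* **cylindrical pores** of known radius with an optional annular cap
  occluding a chosen fraction of the mouth aperture (fraction 1 seals
  it — the fully plugged contrast case).

The toy association runs 20 replicas for 50 ns at a 500 fs step
(noise displacement ≈0.45 Å per step, under half a grid cell; the
field is far smoother than a production all-atom map, which is what
permits the longer step), D_t = 50 Å²/ns, D_r = 5 rad²/ns, within a
60 Å wall.  What passing shows: the force field, restraints,
propagator and analyses compose correctly — replicas released at
random azimuths find, bind and stay at the charged patch, and the
recovered hot spot follows the patch when it is moved.  What it does
not show: force-field realism for actual proteins (bead charges and
the uniform dielectric are caricatures), kinetics (the diffusion
constants and well depths are chosen for rapid convergence), or any
membrane chemistry.

## Numerical choices and edge cases

* Deposition conserves totals exactly; tested to 1e-9.
* Maps are finite by construction (clamps at ±cap); interpolation
  outside a grid follows the map's declared policy (zero, clamp to
  edge, or error).
* Quaternions renormalise every step and on trajectory I/O; the
  trajectory writer emits ≥9 significant digits so round trips
  preserve poses to 1e-9.
* Degenerate inputs raise errors naming the offending atom, line or
  residue (zero-width sample distributions, non-monotone times,
  overlapping initial poses, unknown elements, clashes below 0.1 Å).
* Ties in clustering and representative selection break on the lowest
  frame index.

## Known limitations

* The built-in electrostatic map has no dielectric boundary or
  membrane slab; import PB maps for quantitative protein work.
* Single mobile body; no hydrodynamic interactions; no internal
  degrees of freedom.
* The LJ maps reduce the category probe to a single sphere (direct
  energy summation rather than orientational averaging over a
  multi-site probe).
* The crossing counter gates on z-thresholds only; lateral gating
  through a specific lumen is available in the validation studies'
  walk generator but is not part of the counter itself.
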