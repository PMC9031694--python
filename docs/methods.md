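# Methods

## The physical problem

Pulsed-field ablation (PFA) for atrial fibrillation delivers microsecond
high-voltage pulses through a multielectrode catheter pressed against the
atrium around a pulmonary-vein orifice.  Tissue exposed to a field magnitude
above the irreversible-electroporation (IRE) threshold — 400 V/cm for
myocardium in this model — dies without heating.  Whether a particular
*discharge mode* (the assignment of the 20 electrodes to positive, ground or
floating roles, possibly in a timed sequence) produces a *continuous,
circumferential, sufficiently deep* lesion ring around the orifice is the
question this package answers by simulation.

## Model

### Phantom

A cylindrical bath of diameter 200 mm: a myocardial slab of thickness
H2 = 10 mm (bottom of the domain) pierced by a vein lumen of diameter
D1 = 25 mm, covered by H1 = 50 mm of blood.  Material properties at 5 kHz,
37 °C:

| material    | σ (S/m)  | εr      |
|-------------|----------|---------|
| myocardium  | 0.137    | 1.28e5  |
| blood       | 0.70     | 5250    |
| Pt electrode| 4.6e6    | 1       |
| catheter    | 1e-5     | 1       |

The five-spline flower catheter lies flat on the myocardium around the
orifice.  Each spline is a planar petal loop carrying four electrodes
(length 2.5 mm, diameter 2.33 mm, end-to-end gap 2.5 mm, so a 5 mm
centre-to-centre pitch) at equal arc spacing straddling the petal tip:
serial order along the loop is i (hub side 1), ii (outer, side 1),
iii (outer, side 2), iv (hub side 2).

### Governing equations

Static conduction: ∇·(σ∇φ) = 0 with Dirichlet potentials on the driven
electrodes (positive at V0, ground at 0) and zero normal flux on the outer
boundary; E = −∇φ.  The biphasic pulse timing (50 µs phases, 50 µs
interphase delay) is carried as metadata only: with static, isotropic
conductivities the pulse count and timing cannot change the field
distribution, so only the plateau amplitude matters, and by linearity the
whole solution scales with V0.  An optional complex-admittivity variant
(σ + i·2πf·ε0εr at 5 kHz) bounds the error of dropping the displacement
term: in the plate geometry it shifts myocardial |E| by ≈3%, far inside
every tolerance used here, which justifies the pure-conduction model.

### Discretisation and solver

Cell-centred finite volumes on a tensor-product rectilinear grid: uniform
fine voxels in a region of interest (|x|,|y| ≤ 30 mm; −10 ≤ z ≤ +4 mm),
geometrically graded (ratio 1.35) out to the 200 mm lateral boundary and the
blood top, so the insulating far boundary is honoured without a uniform
200 mm fine grid.  Two-point flux with series (distance-weighted harmonic)
face conductivities conserves current exactly across material jumps.  The
resulting SPD system is solved by conjugate gradients, preconditioned with
a geometric-aggregation multigrid V-cycle (2×2×2 aggregates, Galerkin coarse
operators, damped-Jacobi smoothing) above 60k unknowns and Jacobi below;
relative tolerance 1e-8, fixed iteration order — reruns are byte-identical.

Driven electrodes are eliminated as Dirichlet over their whole interior
(platinum is 7 orders more conductive than tissue).  Undriven electrodes are
open-circuit by default — a disconnected generator channel carries no
current, so the electrode behaves like the polymer it is mounted on; the
isolated-conductor alternative (each floating electrode merged into one
equipotential unknown) is available via `SolverOptions.float_conductors`
for sensitivity analysis and changes the headline metrics only marginally.

The cell field is reconstructed flux-consistently: each cell's normal
component is the face conduction flux divided by the cell's own σ, which
recovers the myocardium-side field correctly at the blood–myocardium
interface (a central difference would smear the 5× conductivity jump and
bias the surface lesion metrics).

Electrode–tissue contact: the insulating petal body lies tangent on the
surface (grazing z = 0, displacing no tissue); only the electrodes dip
`contact_embed` (default 0.5 mm) into the top voxel layer to guarantee
galvanic contact after rasterisation.  Embedding the polymer as well carves
an insulating trench along every petal that suppresses genuine surface
lesion and punches artificial leak channels through the ring-closure test —
a correctness trap worth recording.

### Discharge modes

* **A** (1 simultaneous step): per petal, ii/iii positive, i/iv ground.
* **B** (1 simultaneous step): per petal, i/iii positive, ii/iv ground.
* **C** (5 sequential steps): step k drives spline k positive and grounds
  the two adjacent splines; the rest float.
* **D** (5 sequential steps): like C but grounding the two non-adjacent
  splines (k+2, k+3).

Sequential steps occur at different times, so fields are never summed:
the composed lesion is the union of per-step threshold masks.  The rotation
strategy re-poses the catheter (+24°, +48°), re-rasterises, re-solves, and
unions lesions across poses.

### Lesion metrics

The effective lesion area (ELA) is {|E| ≥ 400 V/cm} restricted to
myocardial voxels.  Metrics (all mm):

* **max depth** — surface minus the deepest lesion cell centre;
* **max surface width** — per 0.5° azimuthal bin, outermost minus innermost
  lesioned radius in the top myocardial layer plus one voxel footprint;
  maximum over bins (radial-band convention; a caliper convention would
  read larger on the same mask);
* **ring closure** at a layer — non-lesion cells must not connect the vein
  rim to the reporting radius (midway between flower radius and ROI edge),
  flood-filled with 8-connectivity so a single-voxel diagonal leak counts
  as a gap (conservative);
* **max continuous circumferential depth** — deepest layer such that every
  layer from the surface down is closed (contiguous-from-surface
  convention, configurable to deepest-closed for sensitivity);
* **gap angles** — angular intervals whose rays meet no lesion voxel;
  sub-degree slivers are rasterisation noise and intervals narrower than
  1° are dropped; when a ring is open purely through a diagonal leak the
  leaking path's interval is reported instead.

## Calibration (two documented protocols)

Two quantities the device literature leaves open were calibrated once
against the benchmark lesion table and then frozen as defaults:

* **Plateau potential V0.**  The generator amplitude is quoted as 1800 V
  peak-to-peak; the plateau electrode-to-ground potential is therefore
  either 900 V (half peak-to-peak) or 1800 V.  Both were run.  1800 V
  reproduces the benchmark surface widths but makes the sequential modes'
  inter-petal fields so strong that C and D form closed rings 3–4 mm deep
  (benchmark: 2.7 and 0.7 mm), inverting the benchmark's B-versus-D
  ordering.  900 V reproduces every qualitative result — mode A open with
  five gaps, B/C/D closed, the C > B > D > A(=0) ordering without rotation
  and A > C > D > B after two rotations — and the closure depths
  quantitatively.  V0 = 900 V is the calibrated default (recorded in each
  run manifest).
* **Petal geometry.**  Flower diameter 36 mm, petal halfwidth 5.5 mm, tip
  taper 0.5, electrode embed 0.5 mm.  The pointed tip concentrates the two
  within-petal dipole rows (mode A depth); the wide base sets the
  inter-petal gaps that decide which modes close.  `calibrate_v0` and
  `calibrate_flower_diameter` re-derive these choices; the diameter scoring
  uses width + closure + depth jointly because width alone is monotone in
  the diameter and would run away from the closure physics.

**Known residual misfit.**  At 900 V the simulated maximum surface widths
are ≈8–9 mm versus the benchmark's ≈11 mm (−25%).  The two constraint
families are geometrically incompatible in this model: an 11 mm radial band
needs the threshold contour near 23 mm radius and hence petal tips ≥20 mm,
which (arc ≥ chord, with the fixed 15 mm electrode chain) forces adjacent
petals' hub-side electrodes ≥11 mm apart — too far for the mode-B
inter-petal bridge to close at 900 V, contradicting the benchmark's closed
mode-B ring.  The closure physics was prioritised; widths are reported as
computed.

## Problem sizes and runtime

Production runs use 0.5 mm in-plane / 0.25 mm vertical ROI voxels
(≈1.4M cells, ≈180k-cell fine myocardial slab; one solve ≈20–30 s on one
core).  The full four-mode, three-pose study is ≈36 solves.  Halving the
in-plane voxel to 0.25 mm changes the headline metrics by less than the
half-voxel metric quantisation (see `convergence_study`); unit tests run a
1 mm demonstration grid.  The `voxel_size`/`voxel_size_z` defaults in
`GeometryConfig` are 0.25 mm; scripts pass the production sizes explicitly.

## What the phantom does and does not emulate

It emulates the geometry, materials and excitation of an idealised
bench model: flat horizontal wall, rotationally symmetric orifice, rigid
centred catheter with perfect pose control, static isotropic
conductivities.  It does not emulate myocardial fibre anisotropy,
field- or pulse-number-dependent conductivity changes during
electroporation, thermal effects, tilted or deformed catheter poses,
trabeculated anatomy, or contact-force variation.  Passing tests therefore
certify the electrostatics and the lesion bookkeeping of the idealised
model — not clinical lesion prediction.

## Numerical choices and degenerate inputs

* Tolerances: solver 1e-8 relative (raising a `SolverError` otherwise);
  current conservation checked to 1%; grid-convergence guard 5%.
* `vein_diameter = 0` degenerates to a solid slab: ring closure is then
  reported as open-by-definition (nothing to encircle).
* Threshold limits: ∞ gives an empty mask, 0 marks all myocardium.
* Ties and orderings are broken deterministically (fixed voxel iteration
  order, no randomised preconditioners); identical configs give
  byte-identical metric CSVs.
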