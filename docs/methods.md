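# Methods

`jointload` reconstructs the loading history of a metacarpophalangeal
(MCP) joint from the three-dimensional voxel architecture of the distal
metacarpal.  This note documents the model, the numerical choices, the
synthetic phantom that stands in for micro-CT data, and the limits of what
the test suite demonstrates.

## The inverse remodelling model

The method rests on a deliberately simple remodelling law: bone tissue is
added or removed unless the local mechanical stimulus equals a remodelling
equilibrium stimulus Ũ.  The local stimulus is the strain energy density
(SED) accumulated over a loading history idealized as `n` discrete posture
load cases, case `i` acting with magnitude `α_i` for `m_i` of `m_tot`
load cycles:

    U(x) = Σ_i (m_i / m_tot) · α_i² · U_i(x)

where `U_i(x)` is the SED at trabecular element `x` under *unit* load case
`i` (100 N resultant).  The most probable loading history is the one that
brings the whole trabecular compartment closest to equilibrium.  With the
combined factors `s_i = α_i² · m_i/m_tot` this is a non-negative least
squares (NNLS) problem,

    minimize over s ≥ 0:   Σ_x [ Ũ − Σ_i s_i U_i(x) ]² ,

solved with `scipy.optimize.nnls` (deterministic, exact active-set
method).  Assuming an equal number of cycles for every case, magnitudes
follow as `α_i = √(n·s_i)`, and the history is condensed into the mean
joint load vector `F̄ = 1/n Σ α_i F_i`.

Parameters and defaults:

| quantity | default | unit | rationale |
|---|---|---|---|
| Ũ (equilibrium stimulus) | 0.02 | MPa | literature estimate for trabecular bone; exposed as `u_tilde` everywhere |
| load-case angles | −75…+75 in 30° steps | deg | six postures from hyperextension to full flexion; wider sets make load areas overlap |
| resultant magnitude | 100 | N | unit load; the recovered α carry the physical scale |
| load area | 40° × 30° | deg | spherical rectangle on the cartilage surface: ±20° in the flexion–extension plane, ±15° radio-ulnar elevation |
| E bone / cartilage | 10 000 / 10 | MPa | standard micro-FE bone modulus; the soft layer only distributes the contact load |
| Poisson ratio | 0.3 | – | both materials |
| trabecular peel | 2 voxels (pipeline: cortical thickness in voxels) | – | strips the cortex off the stimulus matrix; the thick diaphyseal cortex would otherwise couple the result to model length |

Only trabecular elements enter the optimization.  The quality of a
prediction is reported as the coefficient of variation (CoV = 100·SD/mean)
of the combined stimulus over those elements, before (`cov_init`, uniform
load scaling — CoV is invariant to the common scale, so unit weights are
used) and after optimization (`cov_opt`).  The CoV uses the population
standard deviation: the element set is the entire population, not a
sample (`ddof` is exposed for the alternative convention).  Elements with
zero SED in all columns are retained by default — they genuinely penalize
homogeneity — with a `drop_zero_rows` switch.

### Sign conventions

Joint coordinate system: x distal (tangent to the dorsal arc), y palmar,
z radio-ulnar, right-handed, origin at the centre of rotation (CoR) of
the metacarpal head.  Nodal forces and the stored `resultant_N` point
*towards* the CoR (joint compression), and nodal force vectors are all
parallel to the resultant, distributed equally over the loaded nodes so
the resultant is exact to machine precision.  Reported load *directions*
use the articular contact ray −F̄, so a single active case at posture θ
reports direction θ, flexion positive — dorsal (knuckle-walking-like)
loading yields negative directions.  The dorsal-arc tilt is likewise
palmar-relative, which makes it invariant under left/right mirroring (an
anatomical angle, not a grid angle).

## Micro-FE

One trilinear hexahedral element per labelled voxel; the 24×24 element
stiffness uses full 2×2×2 Gauss quadrature (exact for this element;
tests cross-check against a 4³-point rule).  SED is evaluated from the
strain at the element centroid, `U = ½ εᵀCε`.  For homogeneous strain
states `Σ U·V_elem` equals the external work `½ fᵀu` exactly (the energy
identity holds to solver tolerance on the patch-test fixtures); on
fields with intra-element strain variation the centroid value drops the
quadratic variation term, so the summed centroid energy slightly
underestimates `½ fᵀu` — the inverse step consumes per-element values,
not the total, and is unaffected.  The proximal face (minimum
distal-coordinate element layer) is fully constrained.

The assembled system is solved either by sparse LU (SuperLU) for models
up to 30 000 free DOFs, or by conjugate gradients with a Jacobi
preconditioner above that — on voxel elasticity graphs SuperLU fill-in
grows steeply, while Jacobi-CG converges in roughly a thousand iterations
at these sizes.  Default relative residual 1e-8 (iteration cap 1e5); the
forward-remodelling loop relaxes this to 1e-6 because its editing rule
consumes stimulus *ranks*, which stabilize long before the last digits.
One factorization/preconditioner serves all six load cases.

Nodal loads are distributed *equally* over the selected cartilage surface
nodes (not area-weighted): the node set is the intersection of the outer
cartilage surface with the spherical rectangle, and equal shares keep the
resultant exact by construction.  The 40° span is assigned to the
flexion–extension plane and the 30° span to radio-ulnar elevation.

## The phantom

No public micro-CT data accompany the workflow, so all validation runs on
a synthetic distal-metacarpal phantom: a hollow shaft of elliptical
cross-section (radio-ulnar half-width 1.6 mm, palmar-dorsal 0.8 of that)
capped by a spherical head (radius 2.04 mm), cortical wall 0.48 mm,
voxel spacing 0.12 mm, trabecular interior carved to 35% porosity by
seeded random ellipsoidal voids (semi-axes 0.25–0.6 mm).  Shaft length
6.84 mm puts the distal-third crop at ≈1.45 head radii, mimicking the
proportions of a real distal third (a much shorter shaft starves the
extension load cases of trabecular load path next to the constrained
face).  The ellipse and an optional dorsal bow make the radio-ulnar
mirror plane unique; the head is an exact sphere and the dorsal surface
an exact arc, so every geometric fit has a known answer.  Every stage is
deterministic given the spec seed.

The phantom is an idealization, deliberately so: no subchondral plate,
no biofidelic trabecular anisotropy or plate/rod architecture, no
grey-value calibration, no scanner noise.  Passing tests demonstrate the
*mechanical and algorithmic* correctness of the pipeline and its ability
to recover imprinted loading signals at desk scale — they do not
demonstrate segmentation robustness on real scans nor species-level
biological claims.

### Forward remodelling (ground-truth imprinting)

To create architectures with a *known* loading history, the trabecular
interior is adapted iteratively: all load cases are solved, the combined
stimulus `Σ s_i U_i` is computed, trabecular surface voxels in the lowest
45% of the surface-stimulus distribution are resorbed, and void voxels
adjacent to trabecular bone whose strongest neighbour exceeds the 85th
percentile are apposed (3 iterations by default).  A connectivity guard
halves the removal set (up to 3 retries) and finally drops orphaned
fragments, keeping the bone one component.  The rule is rank-based and
therefore scale-free; a calibration step pins the mean stimulus to Ũ so
the imprinted history has a physically meaningful level.  This rule is
**not** a validated biological remodelling model — it is a generator of
test architectures, and only its output property is load-bearing: the
adapted bone is measurably closer to equilibrium under its history
(summed squared deviation from Ũ decreases), and the inverse pipeline
recovers the dominant posture and mean direction from it.

Validation histories cycle dorsal-dominant (α = 1.7, 1.3, 0.8, 0.45,
0.25, 0.15 from −75° to +75°), palmar-dominant (reversed) and mixed
(peaked at ±15°), with ±5% per-case jitter — the contrast between
habitual hyperextension (knuckle-walking) and flexed grasping.

## Geometry pipeline choices

* **Symmetry plane.** Reflective-symmetry search maximizing Dice overlap
  between the envelope-filled image and its mirror, restricted to planes
  containing the long axis (the radio-ulnar plane always does), swept
  coarse (2°) over the transverse orientation and refined (to 0.25° and
  quarter-voxel offsets) over both normal angles and offset.  Internal
  voids are filled first — the envelope is symmetric, the random pore
  pattern is not.  The working resolution adapts so the search sees
  several thousand foreground voxels; on head-dominated crops a too-coarse
  grid lets spurious planes through the near-spherical head tie at
  Dice ≈ 1.
* **Head circle / CoR.**  Distal-facing boundary pixels of the mid-plane
  slice seed a Kåsa + robust geometric circle fit; the estimate is then
  refined by (a) per-angular-bin outermost raw slab voxels (morphological
  contour extraction flattens sub-voxel detail) and (b) a 3-D sphere fit
  to the articular cap surface, which has ~30× more points than any single
  slice.  All surface radii carry a +h/2 correction (outermost voxel
  centres sit half a voxel inside the surface).  Recovery on phantoms:
  CoR within 0.1 voxel, R_H within 0.5%.
* **Dorsal arc.**  Per-column v-extremes of the mid-plane slab over the
  central 50% of bone length (head bulb excluded); parabola fits on both
  contours decide — with a 2σ significance test and a cross-side
  consistency requirement (same curvature sign, radii within 2×) —
  whether the shaft is measurably bent; a circle refinement seeded in the
  correct curvature basin gives R_B.  Straight shafts report R_B = ∞ and
  zero tilt; the palmar side is then resolved by an explicit
  `palmar_hint` (phantoms are straight by default; on real bones the bow
  resolves it).  At 0.12 mm spacing an arc is only identifiable when its
  sagitta over the fit window clears the voxel size, i.e. on long shafts.
* **Cartilage.**  Voxels between the bone envelope and the sphere of
  1.2·R_H around the CoR, restricted to the distal band
  (x ≥ −R_H·sin 75°) and to ±30° elevation about the flexion–extension
  plane (the load areas need ±15°), grown from the bone surface by at
  most the nominal shell thickness — this implements the "crop lateral
  and proximal excess" step and keeps the soft (10 MPa) layer from
  inflating the model.  Bone protruding through the cartilage surface
  inside the band triggers a warning with a count.
* **Proximal seal.**  On distal-third crops the cut face exposes the pore
  network, so envelope filling seals against the first bone slice before
  `binary_fill_holes`; otherwise the trabecular mask collapses.

## Degenerate inputs and tie-breaks

Empty masks, all-zero stimulus matrices, zero-mean CoV fields, degenerate
load areas, collinear circle points, unconstrained models and
disconnected label images all raise typed exceptions
(`jointload.errors`).  NNLS zeros are genuine (active constraints), and
`α_6/α_1` with `α_1 = 0` reports NaN rather than raising.  Sorting makes
load-case order independent of the angle order supplied.

## Problem sizes

The default validation campaign uses six phantoms at 0.12 mm spacing;
each cropped model has ≈20 000 elements (≈75 000 DOFs) and is solved for
six load cases per remodelling iteration (three iterations) plus the
final inversion.  These sizes were chosen so a full campaign, including
all FE solves, completes in minutes on a single CPU core while keeping
≳3 000 trabecular elements in the stimulus matrix; the pipeline itself
is size-agnostic.

## Known limitations

* Articular contact is not modelled; loads are prescribed tractions on an
  idealized cartilage cap.
* Load magnitudes from NNLS are comparative, not absolute in vivo forces;
  they inherit the Ũ calibration and the equal-cycle assumption.
* The forward remodelling rule is a synthetic-data device; agreement
  between imprinted and recovered histories on phantoms does not validate
  the remodelling biology.
* The geometric fits assume a roughly metacarpal-like topology (single
  head, one shaft); they are not general long-bone tools.
* `cov_init`/`cov_opt` on phantoms are not comparable in magnitude to
  values measured on real trabecular architectures.
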