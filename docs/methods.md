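# Methods

## The measurement model

A segment's inertial properties are measured indirectly. The frozen
segment is strapped into a close-fitting Styrofoam holder whose own
mass, CoM and inertia tensor are known; the composite is swung as a
small-amplitude compound pendulum about each of six axes marked on the
box — the three orthogonal box axes xx, yy, zz and three coplanar skew
axes xy, xz, yz, each at an angle θ from the second axis of its pair.
For small amplitudes the period obeys T = 2π√(I_pivot/(m g l)), so the
moment about the pivot is I_pivot = m g l T²/(4π²). Subtracting the
empty-box pivot moment and the parallel-axis term m_s·l_s² leaves the
segment's moment about its own CoM.

The three primary axes give the tensor diagonal. Each skew-axis moment
I\* is the quadratic form uᵀIu of the (still unknown) full tensor along
u = sinθ·ê_a + cosθ·ê_b; solving that form for the off-diagonal term
gives

    P_ab = [I_bb + I_aa·tan²θ − (1 + tan²θ)·I*] / (2 tanθ).

**Sign convention.** Products are stored in mass-integral form
P_ab = ∫ab dm; the inertia *matrix* off-diagonals are −P_ab. Under this
convention the recovery formula above is the exact algebraic inverse of
the quadratic form for all θ in (0, π/2) — a property-tested identity,
not an approximation. All three moments of a skew recovery must refer
to axes through one common point (here the segment/composite CoM).

**Assumptions.** Small-angle simple harmonic motion (period independent
of amplitude; synthetic swings are generated at ≤10° equivalent
amplitude), a rigid pendulum rotating about the frame pivot, and uniform
density within each segment. g defaults to 9.81 m/s² and θ to 45°,
both overridable.

## Period estimation

A recorded trace is reduced to a period in two stages:

1. **Zero crossings.** The mean-removed signal's crossings are located
   by linear interpolation between samples. Noise produces bursts of
   spurious crossings near every true crossing; gaps below 30 % of the
   largest inter-crossing gap (the largest gap is ≈T/2 by construction)
   are collapsed into one crossing at the burst's mean time. Consecutive
   crossings are half a period apart; the least-squares slope of
   crossing time against half-cycle index, doubled, is the initial
   period estimate. At least 3 full cycles are required.
2. **Sinusoid refinement** (default on). The period is polished by a
   whole-trace least-squares sinusoid fit: for a trial frequency the
   amplitude, phase and offset enter linearly, so the fit is a bounded
   1-D search (±5 % around the crossing estimate) over frequency.

The refinement matters because the extraction is ill-conditioned: the
pivot moment is dominated by m·l², so a relative period error δT/T is
amplified into the CoM tensor by roughly 2·(m l²/I_com) — a factor of
10–100 for compact segments. Crossing times alone carry too much jitter
at realistic noise; the whole-trace fit brings δT/T to the ~10⁻⁴ level
that recovery needs. Periods are additionally averaged over three
successive trials per axis, matching the measurement protocol.

## Closed-form solids and the voxel oracle

Segments are modelled as five homogeneous solids, long axis on z,
proximal end at z = 0: cylinder, rectangular pyramid, cone, conical
frustum, ellipsoid. Cylinder and ellipsoid use the textbook tensors;
cone, frustum and pyramid are evaluated by exact polynomial integration
of the stacked-slab integrals (e.g. I_xx = ρ∫[(π/4)r⁴ + πr²(z−z̄)²]dz
with r(z) linear), which reduces to the textbook forms in the
cylinder/cone limits and is exact for the frustum without a separate
branch.

The independent oracle is a deterministic midpoint-rule voxel grid
(default 200³ cells over the bounding box; no randomness, so oracle
tests need no seeds). All second moments reduce to 1-D/2-D marginal
sums of the boolean occupancy array. For these convex shapes the
discretization error is O(1/N²) on the mass and well below 1 % on
tensor components at N = 200, the agreement tolerance used throughout;
resolutions below 50 are refused.

## Reference tables and scaling

The packaged tables carry, per segment: mass fraction, CoM position as
a fraction of segment length from each endpoint, density, volume, and
the six inertia components with SDs, plus a per-segment map from box
axes to anatomical axes (yy is flexion/extension everywhere). Inertia
values are stored in units of 10⁻⁴ kg·m² with an explicit `scale`
field — the source table's header unit is inconsistent with its own
magnitudes by four orders, and the 10⁻⁴ scale is the one consistent
with the regression equations evaluated at cohort-mean body mass. All
accessors return SI.

Two data quirks ship as printed and are surfaced by validators rather
than repaired: the tail row violates the perpendicular-axis inequality
(8.21 + 48.50 < 60.70 in table units, with enormous negative P_xz and
P_yz SDs), and the printed head volume (1000 cm³) is inconsistent with
the head's own mass and density (which imply ≈2822 cm³; every other
segment closes within ~5 %, the tail at 5.3 % owing to its
two-significant-figure mass fraction).

Scaling to a target dog uses the standard normalisation: mass scales
with body mass, CoM with segment length, tensor components with
(body mass/36.8)·(length/L_ref)². The reference length L_ref is not
part of the measured tables; it is derived once per segment as the
length of the uniform *equivalent cylinder* that simultaneously matches
the segment's mean mass, volume and flexion/extension moment — the
larger root of the cubic m·L³ − 12·I·L + 3mV/π = 0, i.e. the elongated
solution appropriate for a transverse axis. The derived values (0.21 m
manus … 0.46 m thorax) are anatomically plausible and ship in the data
file; `scripts/regenerate_reference.py` recomputes them. Because the
reference tables report no lateral or dorso-ventral CoM offsets, scaled
CoMs sit on the proximal–distal axis and the output carries an explicit
on-axis flag. Body masses outside the cohort range [34.29, 39.41] kg
trigger an extrapolation warning, not an error.

## Regression

Every published equation has the fixed family
value = β₀·a + β₁·G + β₂ with a the whole-body mass and G a geometry
regressor; for the MoI equations G is additionally multiplied by a.
The transcription ships as one YAML entry per equation (44 rows:
11 masses, 33 MoIs) with per-row notes. Two parsing rules make the
printed right-hand sides dimensionally homogeneous and are applied
uniformly: a trailing `+b²` binds into the bracketed geometry term
(`0.00223a(c/π)²+b²` ⇒ 0.00223·a·((c/π)²+b²)), and `0.076c²+b²` is one
regressor — 0.076 ≈ 3/(4π²) converts a circumference to 3r² with
r = c/2π, the transverse-cylinder form (3r²+L²)/4. Double-leading-zero
typography is normalized; two intercepts that cannot be checked
independently are kept as printed and flagged. The axial frustum term
(c⁵−d⁵)/(c³−d³) is continuous at c = d with analytic limit (5/3)c².

Predictions outside the calibration body-mass range, and non-positive
predictions, are returned with warnings and validity flags — the user
decides, mirroring how negative extracted MoIs are handled on the
measurement side.

Refitting is plain OLS (via statsmodels) of an observed quantity on
[a, G, 1] with n ≥ 4 and a rank check; shape selection fits each
candidate G and ranks by R², breaking ties toward fewer coefficients
then lexically. The repeatability filter is the paired two-sided t-test
computed from first principles (t = mean(d)/(sd(d)/√n), p from the
t(n−1) CDF; zero-variance differences give p = 1 when the mean is also
zero, else p = 0), cross-checked in tests against an independent
statistics routine.

## The synthetic-data generator

The generator emulates the study conditions: virtual dogs with body
mass uniform on [34.29, 39.41] kg; per-segment mass fractions and
densities drawn lognormally around the reference values at the CVs
implied by the packaged SDs; segment lengths lognormal around L_ref at
5 % CV (the tables give no length dispersions); fractions renormalised
so segment masses sum to the body mass exactly. Each segment becomes
the solid its published equations imply (cylinders for slender limb
segments, frusta for tapering trunk/neck segments with fixed taper
ratios 0.75–1.3, a pyramid for the pes, an ellipsoid for the head, a
cone for the tail), sized to the drawn mass, volume and length, and the
morphometric record is *derived from the generating solids*
(circumference = 2πr, lengths and breadths read off the geometry), so
regression tests have exact ground truth. One global seed fans out to
per-segment substreams via `SeedSequence(entropy=(seed, stream_index))`
with the stream index fixed by the 17-segment order, so adding a
segment never perturbs the others' draws.

Pendulum sessions place each segment centred in its holder (segment CoM
at the box CoM) with a random misalignment tilt of up to 10°, which is
what produces nonzero products in the box frame; the holder is a solid
foam cuboid (30 kg/m³, edges 1.2× the solid's bounding extents) and the
pivot-to-CoM length adapts to the box (0.7× the largest edge, minimum
0.15 m). Traces are SHM at 100 Hz for 20 cycles plus white Gaussian
noise at a stated fraction of the amplitude, three trials per axis.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: segments are homogeneous solids with
clean symmetry (real segments have inhomogeneous tissue and irregular
shape, so real products and regression scatter are larger); pendulum
damping, large-amplitude corrections, string compliance and pivot
friction are absent; morphometric "measurements" are exact functions of
the geometry rather than tape-measure readings; and the
frozen-in-stance posture effects on dimensions are not modelled.
Recovery results therefore demonstrate the *correctness and
conditioning of the computations*, not field accuracy of the protocol.

## Problem sizes and numerical defaults

The analysis drivers and the acceptance script use sizes chosen to make
the statistics stable while keeping each run in seconds: 25 random
solids per shape (100 per shape in the test suite) at voxel resolution
200; 10–20 noisy-session seeds × 11 segments; 50 cohort seeds at n = 12
with 1 % observation noise. Skew-angle recoveries refuse θ within 10⁻⁶
of 0 or π/2; the frustum regressor switches to its analytic limit
within relative 10⁻⁹ of c = d; model export embeds a schema version and
round-trips losslessly through JSON and YAML.

## Known limitations

- The right-brachium frame reversal is encoded as a y-axis reflection
  (P_xy, P_yz negate); the source figure shows the reversal but not the
  handedness bookkeeping, so consumers should treat reflected products
  as convention-dependent.
- The equivalent-cylinder L_ref is a modelling construct; for the head
  (whose printed volume is internally inconsistent) it rests on the
  printed volume as shipped.
- Shape selection cannot distinguish near-collinear geometry terms: the
  two transverse-cylinder variants (0.076c²+b² vs (c/π)²+b²) differ
  only in the circumference weight and tie in practice (see
  `analysis/04_refit_regressions.py`).
- The model export is a parameter file, not a kinematic chain: joint
  centres and posture are out of scope, and segment tensors are valid
  for the frozen-stance configuration they describe.
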