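# caninebsp — body segment parameters of the German Shepherd dog

Inverse-dynamics gait analysis needs, for every body segment, its mass,
centre of mass (CoM) and inertia tensor — the *body segment parameters*
(BSPs). This package provides a complete, working BSP toolkit for the
German Shepherd, built around a cadaver-segmentation data set of six
adult male police-service dogs (mean body mass 36.8 kg) divided into 17
segments: head, neck, thorax, abdomen, tail, and left/right brachium,
antebrachium, manus, thigh, crus, pes.

It contains four things a canine biomechanist needs:

1. **The measurement computations.** Segment moments of inertia come from
   the compound-pendulum method: a frozen segment in a calibrated
   Styrofoam holder is swung about six marked axes (xx, yy, zz and three
   coplanar 45° skew axes), and

   $$I_\text{pivot} = \frac{m\,g\,l\,T^2}{4\pi^2},\qquad
     I^\text{CoM}_\text{seg} = \frac{m_c g l_c T_c^2 - m_b g l_b T_b^2}{4\pi^2} - m_s l_s^2,$$

   with subscripts *c* (composite), *b* (empty box), *s* (segment). The
   products of inertia follow from the skew-axis moments,

   $$P_{ab} = \frac{I_{bb} + I_{aa}\tan^2\theta - (1+\tan^2\theta)\,I^*}{2\tan\theta},$$

   which is the exact algebraic inverse of the quadratic form
   $I^* = u^\mathsf{T} I u$ for the skew axis
   $u = \sin\theta\,\hat e_a + \cos\theta\,\hat e_b$. CoMs come from
   knife-edge moment balance. (`caninebsp.pendulum`, `caninebsp.inertial_math`)

2. **The reference tables.** Normalised segment masses, CoM ratios,
   densities, volumes and full 6-component inertia descriptions (with
   SDs) for all segments, with mass- and length²-scaling to a target dog.
   Known quirks of the measured data ship as printed and are *reported*,
   not silently fixed — the tail tensor violates the perpendicular-axis
   inequality, and the printed head volume is inconsistent with the
   head's own mass and density. (`caninebsp.bsp_reference`)

3. **The 44 regression equations** (11 masses, 33 MoIs) predicting BSPs
   from whole-body mass *a* and external morphometrics via geometric
   regressors (cylinder, conical frustum, rectangular box, ellipsoid
   forms), each of the form $y = \beta_0 a + \beta_1 G + \beta_2$ — plus
   the other direction: OLS refitting on cohorts with R²-based shape
   selection and the paired-t repeatability filter.
   (`caninebsp.regression`)

4. **A 17-segment rigid-body model builder** with JSON/YAML export,
   left/right mirroring and the right-brachium frame reversal, and a
   synthetic-data generator (virtual dogs assembled from homogeneous
   geometric solids, forward-simulated pendulum sessions, cohorts with
   known ground truth) that makes every pipeline stage testable.
   (`caninebsp.model_builder`, `caninebsp.synthetic_data`)

## Worked example

```python
from caninebsp.bsp_reference import lookup, scale_to_dog
from caninebsp.regression import MorphometricRecord, equations_for, evaluate
from caninebsp.synthetic_data import nominal_dimensions

ref, moi = lookup("thigh")
print(f"thigh: {ref.mass_fraction:.4f} of body mass, density {ref.density:.0f} kg/m^3")

seg = scale_to_dog("thigh", body_mass=36.8, segment_length=0.25)
print(f"mass {seg.mass:.3f} kg, CoM {seg.com_from_proximal*100:.1f} cm from the hip,")
print(f"I_flx/ext (yy) {seg.tensor.i_yy*1e4:.1f} x 1e-4 kg m^2")

rec = MorphometricRecord(36.8, nominal_dimensions("thigh"))
print(f"regression thigh mass: {evaluate(equations_for('thigh','mass')[0], rec).value:.3f} kg")
```

prints

```
thigh: 0.0451 of body mass, density 940 kg/m^3
mass 1.660 kg, CoM 11.2 cm from the hip,
I_flx/ext (yy) 93.8 x 1e-4 kg m^2
regression thigh mass: 1.660 kg
```

The reference thigh is 4.51 % of body mass (1.660 kg at 36.8 kg); on a
25 cm thigh its CoM sits 44.6 % of the way down from the greater
trochanter; the flexion/extension moment is scaled from the packaged
value by (length/L_ref)². The regression equation, evaluated at the
reference segment's nominal dimensions, reproduces the same mass — the
mass table and the mass equations are mutually consistent.

There is also a CLI (`caninebsp reference|predict|fit|extract|build|simulate`)
for file-based use; run any subcommand with `--help`.

## Analysis scripts

The `analysis/` directory holds the narrative drivers, each writing its
tables under `results/`:

| script | what it shows |
|---|---|
| `01_audit_reference_tables.py` | mass/CoM closures, the tail and head data quirks |
| `02_validate_solid_oracle.py` | closed-form tensors vs voxel integration (<0.1 %) |
| `03_recover_pendulum_tensors.py` | six-axis identifiability, noise-free and at 5 % noise |
| `04_refit_regressions.py` | coefficient recovery and shape selection on n=12 cohorts |
| `05_build_reference_model.py` | the exported 17-segment reference dog model |

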