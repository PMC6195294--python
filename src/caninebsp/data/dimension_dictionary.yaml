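# Data dictionary for morphometric dimension keys used by the regression
# equations.  Record columns are named `<segment>.<letter>` (metres) plus
# `body_mass_kg`; the letter definitions below are the measurement
# protocol's own wording.  `ambiguous: true` marks a definition whose
# second landmark is not fully specified in the protocol.

a: "Whole body mass (kg) -- shared by every equation; column body_mass_kg"

manus:
  b: "length of caudal edge of metacarpal pad to podactylion III (m)"
  c: "Bistyloidal circumference at carpal joint (m)"
antebrachium:
  b: "length of antebrachium -- proximal to distal joint centers (m)"
  c: "Bistyloidal circumference at carpal joint (m)"
brachium:
  b: "length of brachium -- proximal to distal joint centers (m)"
  c: "circumference at highest point in the axilla, perpendicular to long axis (m)"
  d: "circumference at olecranon process across epicondyles (m)"
pes:
  b: "length of proximal joint center to podactylion III (m)"
  c: "breadth across metatarsal phalangeal joints (m)"
  d: "depth of pes at midpoint between malleoli and base of the pes (m)"
crus:
  b: "length of crus -- proximal to distal joint centers (m)"
  c: "circumference of hock at malleoli (m)"
thigh:
  b: "mid centroid of femoral head (m)"
  b_ambiguous: true   # distal endpoint of this length is not stated
  c: "circumference of stifle joint at mid-patella (m)"
head:
  b: "length of head -- atlas/axis joint center to end of nose (m)"
  c: "ecto-orbitale breadth (m)"
neck:
  b: "length from axis (base of the head) to C7 (m)"
  c: "circumference at axis/atlas joint (base of head) (m)"
  d: "circumference at mid length, halfway between the axis and C7 (m)"
  e: "circumference at C7/T1 (base of neck/shoulders) (m)"
abdomen:
  b: "circumference at T13/L1 joint (base of ribs) (m)"
  c: "length of T13/L1 to L7/S1 (spinous processes) (m)"
  d: "circumference at level of waist (narrowest point) (m)"
thorax:
  b: "circumference at C7/T1 (base of neck/shoulders) (m)"
  c: "length of C7/T1 joint center to T13/L1 joint center (m)"
  d: "circumference at T13/L1 joint (base of ribs) (m)"
tail:
  b: "length from sacrum to tip of tail (m)"
  c: "circumference at sacrum (m)"
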