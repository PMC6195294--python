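# Normalised segment masses, CoM ratios, densities and volumes for the
# German Shepherd reference cohort (6 adult male police service dogs,
# left/right limb values pooled).  One entry per anatomical segment name.
#
# Columns: mass_fraction = segment mass / whole-body mass; com_ratio_prox
# and com_ratio_dist = CoM distance / segment length measured from the
# proximal(cranial) and distal(caudal) endpoints; density kg/m3; volume cm3.
# Every quantity carries its cohort SD.
#
# l_ref_m is a derived quantity (not measured): the length of the uniform
# equivalent cylinder that reproduces the cohort-mean mass, volume and
# flexion/extension MoI simultaneously (larger root of
# m(3V/(pi L) + L^2)/12 = I_flx_ext).  Regenerate with
# scripts/regenerate_reference.py.

study:
  n_dogs: 6
  sex: male
  occupation: police service (active or recently retired)
  body_mass_mean_kg: 36.8
  body_mass_range_kg: [34.29, 39.41]
  age_mean_years: 4.75
  cut_waste_kg_per_dog: 0.182

segments:
  manus:
    endpoints: "Mid carpus to distal 3rd phalanx"
    mass_fraction: 0.0072
    mass_fraction_sd: 0.0002
    com_ratio_prox: 0.4848
    com_ratio_prox_sd: 0.0089
    com_ratio_dist: 0.5185
    com_ratio_dist_sd: 0.0091
    density_kg_m3: 934.02
    density_sd: 18.10
    volume_cm3: 287.0
    volume_sd: 12.9
    l_ref_m: 0.207849
  antebrachium:
    endpoints: "Lateral epicondyle to carpal joint"
    mass_fraction: 0.0138
    mass_fraction_sd: 0.0005
    com_ratio_prox: 0.3941
    com_ratio_prox_sd: 0.0055
    com_ratio_dist: 0.6076
    com_ratio_dist_sd: 0.0053
    density_kg_m3: 977.54
    density_sd: 17.10
    volume_cm3: 521.0
    volume_sd: 30.7
    l_ref_m: 0.247915
  brachium:
    endpoints: "Glenohumeral joint to lateral epicondyle"
    mass_fraction: 0.0240
    mass_fraction_sd: 0.0013
    com_ratio_prox: 0.4183
    com_ratio_prox_sd: 0.0183
    com_ratio_dist: 0.5869
    com_ratio_dist_sd: 0.0197
    density_kg_m3: 974.37
    density_sd: 12.71
    volume_cm3: 908.0
    volume_sd: 86.2
    l_ref_m: 0.235981
  pes:
    endpoints: "Tuber calcaneus to distal 3rd phalanx"
    mass_fraction: 0.0082
    mass_fraction_sd: 0.0002
    com_ratio_prox: 0.5140
    com_ratio_prox_sd: 0.0044
    com_ratio_dist: 0.4880
    com_ratio_dist_sd: 0.0042
    density_kg_m3: 1013.58
    density_sd: 12.45
    volume_cm3: 305.0
    volume_sd: 12.6
    l_ref_m: 0.260456
  crus:
    endpoints: "Femoral condyle to lateral malleolus"
    mass_fraction: 0.0150
    mass_fraction_sd: 0.0006
    com_ratio_prox: 0.3659
    com_ratio_prox_sd: 0.0113
    com_ratio_dist: 0.6364
    com_ratio_dist_sd: 0.0111
    density_kg_m3: 1010.60
    density_sd: 19.38
    volume_cm3: 548.0
    volume_sd: 33.3
    l_ref_m: 0.242301
  thigh:
    endpoints: "Greater trochanter to femoral condyle"
    mass_fraction: 0.0451
    mass_fraction_sd: 0.0028
    com_ratio_prox: 0.4463
    com_ratio_prox_sd: 0.0115
    com_ratio_dist: 0.5601
    com_ratio_dist_sd: 0.0124
    density_kg_m3: 939.78
    density_sd: 13.40
    volume_cm3: 1760.0
    volume_sd: 183.0
    l_ref_m: 0.270664
  head:
    endpoints: "Inion to prosthion"
    mass_fraction: 0.0770
    mass_fraction_sd: 0.0039
    com_ratio_prox: 0.3165
    com_ratio_prox_sd: 0.0081
    com_ratio_dist: 0.6842
    com_ratio_dist_sd: 0.0082
    density_kg_m3: 1004.18
    density_sd: 20.29
    volume_cm3: 1000.0
    volume_sd: 20.3
    l_ref_m: 0.319834
  neck:
    endpoints: "Atlas/axis to C7/T1"
    mass_fraction: 0.0661
    mass_fraction_sd: 0.0068
    com_ratio_prox: 0.5627
    com_ratio_prox_sd: 0.0122
    com_ratio_dist: 0.4431
    com_ratio_dist_sd: 0.0128
    density_kg_m3: 970.01
    density_sd: 25.53
    volume_cm3: 2550.0
    volume_sd: 292.0
    l_ref_m: 0.246016
  abdomen:
    endpoints: "T13/L1 to tail base"
    mass_fraction: 0.2415
    mass_fraction_sd: 0.0153
    com_ratio_prox: 0.4677
    com_ratio_prox_sd: 0.0047
    com_ratio_dist: 0.5343
    com_ratio_dist_sd: 0.0050
    density_kg_m3: 963.89
    density_sd: 7.71
    volume_cm3: 9260.0
    volume_sd: 714.0
    l_ref_m: 0.419210
  thorax:
    endpoints: "C7/T1 to T13/L1"
    mass_fraction: 0.3806
    mass_fraction_sd: 0.0101
    com_ratio_prox: 0.5368
    com_ratio_prox_sd: 0.0110
    com_ratio_dist: 0.4670
    com_ratio_dist_sd: 0.0109
    density_kg_m3: 1083.39
    density_sd: 83.44
    volume_cm3: 13300.0
    volume_sd: 1070.0
    l_ref_m: 0.463284
  tail:
    endpoints: "Base of tail to tip"
    mass_fraction: 0.0080
    mass_fraction_sd: 0.0005
    com_ratio_prox: 0.3128
    com_ratio_prox_sd: 0.0158
    com_ratio_dist: 0.6892
    com_ratio_dist_sd: 0.0162
    density_kg_m3: 900.63
    density_sd: 63.73
    volume_cm3: 345.0
    volume_sd: 45.1
    l_ref_m: 0.443788
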