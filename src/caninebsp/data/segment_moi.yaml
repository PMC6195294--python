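# Segment moments and products of inertia for the German Shepherd
# reference cohort, about box axes at the segment CoM, left/right pooled.
#
# Values are stored in units of `scale` kg.m2 (i.e. multiply by scale to
# get SI).  The source table is headed kg.m2, but the magnitudes are four
# orders too large for segments of these masses (a 0.27 kg manus cannot
# have I = 6.37 kg.m2); the 1e-4 kg.m2 scale is consistent with the
# regression-equation outputs evaluated at cohort-mean body mass, and all
# package accessors return SI.
#
# axis_map ties the box axes (xx, yy, zz) to anatomical rotation axes per
# segment, matching the row labels of the regression tables; yy is the
# flexion/extension axis for every segment.
#
# The tail row is transcribed as measured even though it violates the
# perpendicular-axis inequality (8.21 + 48.50 < 60.70) and carries a huge
# negative p_xz / p_yz: validators must report, not reject, this row.

scale: 1.0e-4

segments:
  manus:
    i_int_ext: 6.37
    i_int_ext_sd: 0.79
    i_abd_add: 10.26
    i_abd_add_sd: 1.25
    i_flx_ext: 9.83
    i_flx_ext_sd: 1.17
    p_xy: 2.64
    p_xy_sd: 1.11
    p_xz: 4.02
    p_xz_sd: 1.01
    p_yz: 1.68
    p_yz_sd: 0.74
    axis_map: {xx: int_ext, yy: flx_ext, zz: abd_add}
  antebrachium:
    i_int_ext: 9.82
    i_int_ext_sd: 1.23
    i_abd_add: 32.68
    i_abd_add_sd: 2.64
    i_flx_ext: 26.86
    i_flx_ext_sd: 1.85
    p_xy: 6.84
    p_xy_sd: 1.12
    p_xz: 24.32
    p_xz_sd: 4.67
    p_yz: -5.33
    p_yz_sd: 5.57
    axis_map: {xx: abd_add, yy: flx_ext, zz: int_ext}
  brachium:
    i_int_ext: 29.87
    i_int_ext_sd: 4.06
    i_abd_add: 51.46
    i_abd_add_sd: 8.07
    i_flx_ext: 43.69
    i_flx_ext_sd: 7.16
    p_xy: 8.85
    p_xy_sd: 3.27
    p_xz: 17.16
    p_xz_sd: 2.96
    p_yz: 19.12
    p_yz_sd: 9.80
    axis_map: {xx: abd_add, yy: flx_ext, zz: int_ext}
  pes:
    i_int_ext: 18.86
    i_int_ext_sd: 1.59
    i_abd_add: 8.93
    i_abd_add_sd: 0.80
    i_flx_ext: 17.34
    i_flx_ext_sd: 0.51
    p_xy: 5.36
    p_xy_sd: 0.82
    p_xz: 7.29
    p_xz_sd: 0.76
    p_yz: 2.40
    p_yz_sd: 0.98
    axis_map: {xx: abd_add, yy: flx_ext, zz: int_ext}
  crus:
    i_int_ext: 15.48
    i_int_ext_sd: 1.95
    i_abd_add: 28.55
    i_abd_add_sd: 1.98
    i_flx_ext: 28.00
    i_flx_ext_sd: 1.69
    p_xy: 3.77
    p_xy_sd: 3.18
    p_xz: 29.28
    p_xz_sd: 2.49
    p_yz: 3.14
    p_yz_sd: 6.80
    axis_map: {xx: abd_add, yy: flx_ext, zz: int_ext}
  thigh:
    i_int_ext: 100.61
    i_int_ext_sd: 9.24
    i_abd_add: 79.74
    i_abd_add_sd: 12.24
    i_flx_ext: 109.91
    i_flx_ext_sd: 11.69
    p_xy: 19.00
    p_xy_sd: 3.27
    p_xz: 28.01
    p_xz_sd: 3.71
    p_yz: 38.78
    p_yz_sd: 3.51
    axis_map: {xx: abd_add, yy: flx_ext, zz: int_ext}
  head:
    i_int_ext: 253.67
    i_int_ext_sd: 5.53
    i_abd_add: 191.61
    i_abd_add_sd: 16.20
    i_flx_ext: 248.60
    i_flx_ext_sd: 10.24
    p_xy: 51.79
    p_xy_sd: 5.16
    p_xz: 78.18
    p_xz_sd: 6.94
    p_yz: 82.20
    p_yz_sd: 7.29
    axis_map: {xx: int_ext, yy: flx_ext, zz: abd_add}
  neck:
    i_int_ext: 155.04
    i_int_ext_sd: 15.89
    i_abd_add: 160.27
    i_abd_add_sd: 11.19
    i_flx_ext: 142.75
    i_flx_ext_sd: 19.62
    p_xy: 50.00
    p_xy_sd: 7.23
    p_xz: 34.66
    p_xz_sd: 3.88
    p_yz: 46.17
    p_yz_sd: 9.04
    axis_map: {xx: int_ext, yy: flx_ext, zz: abd_add}
  abdomen:
    i_int_ext: 1164.68
    i_int_ext_sd: 185.52
    i_abd_add: 737.53
    i_abd_add_sd: 105.81
    i_flx_ext: 1457.73
    i_flx_ext_sd: 213.35
    p_xy: 162.88
    p_xy_sd: 20.11
    p_xz: 246.50
    p_xz_sd: 58.04
    p_yz: 70.23
    p_yz_sd: 283.44
    axis_map: {xx: int_ext, yy: flx_ext, zz: abd_add}
  thorax:
    i_int_ext: 2811.71
    i_int_ext_sd: 160.47
    i_abd_add: 1350.62
    i_abd_add_sd: 35.68
    i_flx_ext: 2825.10
    i_flx_ext_sd: 170.99
    p_xy: 318.51
    p_xy_sd: 10.12
    p_xz: 701.83
    p_xz_sd: 43.53
    p_yz: 1004.15
    p_yz_sd: 153.99
    axis_map: {xx: int_ext, yy: flx_ext, zz: abd_add}
  tail:
    i_int_ext: 8.21
    i_int_ext_sd: 1.41
    i_abd_add: 60.70
    i_abd_add_sd: 4.37
    i_flx_ext: 48.50
    i_flx_ext_sd: 4.27
    p_xy: 21.19
    p_xy_sd: 2.41
    p_xz: -435.32
    p_xz_sd: 1915.34
    p_yz: -2039.36
    p_yz_sd: 628.28
    axis_map: {xx: abd_add, yy: flx_ext, zz: int_ext}
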