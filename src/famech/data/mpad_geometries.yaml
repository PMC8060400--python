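# mPAD micropost array geometries, labelled by the effective substrate
# stiffness each array presents to cells.  Spring constants are the
# published per-array values; the PDMS Young's modulus is calibrated by
# inverting k = 3*pi*E*D^4/(64*L^3) on the reference row and shared by
# all geometries (the arrays are cast from the same elastomer).
reference_label: "5 kPa"
posts:
  - label: "5 kPa"
    height_um: 8.3
    diameter_um: 1.83
    spring_constant_nn_per_um: 7.22
  - label: "14 kPa"
    height_um: 6.1
    diameter_um: 1.83
    spring_constant_nn_per_um: 18.17
  - label: "25 kPa"
    height_um: 5.0
    diameter_um: 1.83
    spring_constant_nn_per_um: 33.03
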