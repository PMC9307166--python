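# Exemplary tri-axial square Helmholtz system.
#
# Schema
# ------
# geometry.pairs: list of coil pairs, each with
#   shape:      square | circular
#   size:       side length a (square) or radius r (circular), meters
#   separation: inter-loop distance d along the axis, meters
#   turns:      windings per loop (integer >= 1)
#   axis:       unit 3-vector, pair symmetry axis
#   center:     3-vector, meters (origin = nominal specimen position)
#   polarity:   serial | anti-serial   (anti-serial = sham/blanked wiring)
# sensor / setup / driver / mea: optional model blocks (see module docs)
# seed: global random seed
#
# The separations below sit at the homogeneity optimum d ~ 0.5445 * a.
geometry:
  pairs:
    - shape: square
      size: 0.223        # a_x = 223 mm
      separation: 0.121425
      turns: 32
      axis: [1.0, 0.0, 0.0]
      center: [0.0, 0.0, 0.0]
      polarity: serial
    - shape: square
      size: 0.400        # a_y = 400 mm
      separation: 0.217802
      turns: 53
      axis: [0.0, 1.0, 0.0]
      center: [0.0, 0.0, 0.0]
      polarity: serial
    - shape: square
      size: 0.162        # a_z = 162 mm
      separation: 0.088210
      turns: 19
      axis: [0.0, 0.0, 1.0]
      center: [0.0, 0.0, 0.0]
      polarity: serial
driver:
  R_shunt: 1.0
  supply: 15.0
  dropout: 4.0
  current_limit: 3.0
  coil_R: 10.1           # x-axis pair; y = 29.9, z = 4.4 ohm
  coil_L: 1.05e-3        # x-axis pair; y = 5.16 mH, z = 0.24 mH
seed: 20220722
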