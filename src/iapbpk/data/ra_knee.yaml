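name: ra
units:
  sf_volume: mL
  sf_ph: dimensionless
  sf_viscosity: cP
  sf_density: g/mL
  sf_velocity: cm/s
  synovium_area: cm^2
  cartilage_area: cm^2
  cartilage_thickness: mm
  n_cartilage_sublayers: count
  intima_thickness: um
  subintima_thickness: um
  blood_flow_density: mL/min/mL
  temperature: K
  synovial_gap_factor: dimensionless
  l_syn: cm
sf_volume: 30.0
sf_ph: 7.7
sf_viscosity: 389.5
sf_density: 1.0
sf_velocity: 1.5
synovium_area: 277.0
cartilage_area: 148.0
cartilage_thickness: 2.5
n_cartilage_sublayers: 10
intima_thickness: 162.0
subintima_thickness: 705.0
blood_flow_density: 0.63
temperature: 310.15
synovial_gap_factor: 0.207
# kept at the healthy default: disease changes the effusion volume, not the
# characteristic hydrodynamic length of the synovium surface
l_syn: 0.0079783393501805
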