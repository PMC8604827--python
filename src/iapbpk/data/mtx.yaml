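# Methotrexate parameter set for the intra-articular case study.
name: methotrexate
units:
  log_p: dimensionless
  d_aqueous: cm^2/s
  reference_solubility: mg/mL
  reference_solubility_ph: dimensionless
  fup: fraction
  rbp: dimensionless
  fu_tissue: fraction
  particle_radius: um
  precipitate_radius: um
  particle_density: g/mL
  mean_precipitation_time: s
log_p: -1.85
d_aqueous: 0.62e-5
reference_solubility: 0.16
reference_solubility_ph: 4.2
fup: 0.66
rbp: 0.79
fu_tissue:
  synovial_fluid: 0.66
  intima: 0.66
  subintima: 0.66
  cartilage: 0.66
particle_radius: 25.0
precipitate_radius: 1.0
particle_density: 1.2
mean_precipitation_time: 900.0
diffusivity_mode:
  synovial_fluid: water
  intima: water
  subintima: water
  cartilage: water
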