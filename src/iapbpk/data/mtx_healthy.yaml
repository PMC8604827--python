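# 5 mg methotrexate solution, 2 mL vehicle, injected into a healthy knee.
physiology: healthy_knee.yaml
compound: mtx.yaml
pk:
  file: mtx_pk.yaml
  body_weight: 70.0
dose:
  route: IA
  amount: 5.0
  vehicle_volume: 2.0
  form: solution
settings:
  duration: 25.0
  output_step: 0.01
output_prefix: mtx_healthy
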