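# 25-kg pig. No richly/poorly split of fat is available for the pig
# (single fat compartment); lung blood volume is not available and defaults
# to zero.
species: pig
body_weight_kg: 25.0
minute_ventilation_l_min: 3.6
alveolar_ventilation_l_min: 2.34
cardiac_output_l_min: 2.060
perfusion_fraction:
  fat: 0.1747
  liver: 0.3052
  richly_perfused: 0.1829
  poorly_perfused: 0.0553
  muscle: 0.2523
  brain: 0.0296
volume_fraction:
  fat: 0.3
  liver: 0.0294
  richly_perfused: 0.0697
  poorly_perfused: 0.1269
  muscle: 0.4
  brain: 0.004
blood_volume_fraction:
  arterial: 0.018
  venous: 0.042
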