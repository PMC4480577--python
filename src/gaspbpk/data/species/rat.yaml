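# 0.25-kg rat. Single fat compartment; no separate poorly perfused tissue
# compartment is defined for the rat.
species: rat
body_weight_kg: 0.25
minute_ventilation_l_min: 0.18
alveolar_ventilation_l_min: 0.117
cardiac_output_l_min: 0.083
perfusion_fraction:
  fat: 0.09
  liver: 0.25
  richly_perfused: 0.484
  muscle: 0.15
  brain: 0.026
volume_fraction:
  fat: 0.07
  liver: 0.04
  richly_perfused: 0.0497
  muscle: 0.676
  brain: 0.0003
blood_volume_fraction:
  arterial: 0.0167
  venous: 0.050
  lung: 0.0074
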