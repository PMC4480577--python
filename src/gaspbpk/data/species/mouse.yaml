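# 0.025-kg mouse. Single fat compartment; no separate poorly perfused
# tissue compartment.
# Note: the source table prints minute ventilation 0.385 and alveolar
# ventilation 0.025 L/min, which is inconsistent with a 32.5 % dead-space
# rule; both are stored exactly as printed and the alveolar value is the one
# the lung-exchange equation consumes.
species: mouse
body_weight_kg: 0.025
minute_ventilation_l_min: 0.385
alveolar_ventilation_l_min: 0.025
cardiac_output_l_min: 0.017
perfusion_fraction:
  fat: 0.09
  liver: 0.25
  richly_perfused: 0.415
  muscle: 0.15
  brain: 0.095
volume_fraction:
  fat: 0.10
  liver: 0.055
  richly_perfused: 0.0454
  muscle: 0.66
  brain: 0.0046
blood_volume_fraction:
  arterial: 0.0110
  venous: 0.0331
  lung: 0.0049
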