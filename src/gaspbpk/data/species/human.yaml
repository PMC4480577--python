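# 70-kg adult male reference physiology.
# Flows in L/min, body weight in kg, all fractions dimensionless.
species: human
body_weight_kg: 70.0
minute_ventilation_l_min: 7.5
alveolar_ventilation_l_min: 4.875
cardiac_output_l_min: 6.0
# Fraction of cardiac output perfusing each compartment.
# The printed fractions sum to 0.9833; the residual 1.67 % of cardiac output
# is routed as a peripheral arteriovenous bypass (not renormalised).
perfusion_fraction:
  fat_rich: 0.04
  fat_poor: 0.01
  liver: 0.26
  richly_perfused: 0.3303
  poorly_perfused: 0.01
  muscle: 0.24
  brain: 0.093
# Fraction of body weight occupied by each compartment.
volume_fraction:
  fat_rich: 0.09
  fat_poor: 0.09
  liver: 0.06
  richly_perfused: 0.0624
  poorly_perfused: 0.24
  muscle: 0.44
  brain: 0.0176
blood_volume_fraction:
  arterial: 0.0209
  venous: 0.0545
  lung: 0.00245
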