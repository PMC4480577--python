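gas,species,compartment,auc_mol_min_per_l,cmax_mol_per_l,t_half_min,t_max_min
xenon,human,blood_venous,1.31e-1,2.54e-3,3.64,42.0
xenon,human,blood_arterial,1.61e-1,2.78e-3,0.21,2.4
xenon,human,liver,1.64e-1,2.98e-3,2.87,33.1
xenon,human,muscle,1.10e-1,2.73e-3,15.83,182.7
xenon,human,fat_rich,1.66e-1,5.46e-3,29.12,336.1
xenon,human,fat_poor,4.41e-2,1.49e-3,30.42,351.1
xenon,human,richly_perfused,1.64e-1,2.94e-3,2.40,27.6
xenon,human,poorly_perfused,1.58e-3,5.23e-4,29.44,339.8
xenon,human,brain,1.73e-1,3.12e-3,2.52,29.1
xenon,pig,blood_venous,8.63e-2,1.77e-3,4.62,53.3
xenon,pig,blood_arterial,1.26e-1,2.16e-3,0.19,2.2
xenon,pig,liver,1.67e-1,2.95e-3,1.59,18.4
xenon,pig,muscle,1.03e-1,2.61e-3,16.91,195.2
xenon,pig,fat,1.64e-1,5.37e-3,28.98,334.5
xenon,pig,richly_perfused,1.54e-1,2.97e-3,5.31,61.3
xenon,pig,poorly_perfused,8.42e-2,2.30e-3,20.40,235.4
xenon,pig,brain,1.37e-1,2.43e-3,1.79,20.7
xenon,rat,blood_venous,9.84e-1,3.41e-3,0.31,3.6
xenon,rat,blood_arterial,1.20,4.05e-3,0.05,0.6
xenon,rat,liver,8.66e-1,2.93e-3,0.35,4.1
xenon,rat,muscle,2.46e-1,1.14e-3,2.29,26.4
xenon,rat,fat,1.52,7.15e-3,2.39,27.6
xenon,rat,richly_perfused,8.74e-1,2.94e-3,0.26,3.0
xenon,rat,brain,1.22,4.11e-3,0.09,1.0
argon,human,blood_venous,3.74e-2,7.02e-4,2.71,31.3
argon,human,blood_arterial,4.41e-2,7.49e-4,0.18,2.1
argon,human,liver,3.21e-2,5.64e-4,1.89,21.8
argon,human,muscle,2.37e-2,5.26e-4,11.25,129.9
argon,human,fat_rich,4.18e-2,1.30e-3,26.55,306.4
argon,human,fat_poor,1.19e-2,3.93e-4,29.48,340.3
argon,human,richly_perfused,4.36e-2,7.70e-4,2.07,23.9
argon,human,poorly_perfused,4.35e-3,1.42e-4,28.93,333.8
argon,human,brain,2.90e-2,5.05e-4,1.46,16.8
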