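# Xenon partition coefficients (Ostwald-type, dimensionless) per species.
# blood_gas is PC_blood:gas; tissue_blood maps compartment -> PC_tissue:blood.
# atmospheric_percent is the ambient atmospheric abundance, % by volume.
gas: xenon
atmospheric_percent: 8.7e-06
blood_gas:
  mouse: 0.207
  rat: 0.207
  pig: 0.11
  human: 0.14
tissue_blood:
  mouse:
    fat: 6.2802
    liver: 0.7246
    richly_perfused: 0.6951
    poorly_perfused: 0.7246
    muscle: 0.7246
    brain: 1.1233
  rat:
    fat: 6.2802
    liver: 0.7246
    richly_perfused: 0.7229
    poorly_perfused: 0.7246
    muscle: 0.7246
    brain: 1.015
  pig:
    fat: 11.8182
    liver: 1.3636
    richly_perfused: 1.3774
    poorly_perfused: 1.3636
    muscle: 1.3636
    brain: 1.1233
  human:
    fat_rich: 9.287
    fat_poor: 9.287
    liver: 1.071
    richly_perfused: 1.071
    poorly_perfused: 1.071
    muscle: 1.071
    brain: 1.123
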