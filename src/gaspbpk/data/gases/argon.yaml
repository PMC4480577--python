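# Argon partition coefficients (Ostwald-type, dimensionless) per species.
# The fat:blood value 4.162 is the ratio of Ostwald solubilities
# (olive oil:gas 0.154) / (blood:gas 0.037); see the partition module.
gas: argon
atmospheric_percent: 1.0
blood_gas:
  mouse: 0.037
  rat: 0.037
  pig: 0.037
  human: 0.037
tissue_blood:
  mouse:
    fat: 4.1622
    liver: 0.7539
    richly_perfused: 1.0663
    poorly_perfused: 0.9987
    muscle: 0.7205
    brain: 0.6747
  rat:
    fat: 4.1622
    liver: 0.7539
    richly_perfused: 1.0323
    poorly_perfused: 0.9987
    muscle: 0.7205
    brain: 0.6747
  pig:
    fat: 4.1622
    liver: 0.7539
    richly_perfused: 1.0506
    poorly_perfused: 0.9987
    muscle: 0.7205
    brain: 0.6747
  human:
    fat_rich: 4.162
    fat_poor: 4.162
    liver: 0.754
    richly_perfused: 1.028
    poorly_perfused: 0.999
    muscle: 0.720
    brain: 0.6751
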