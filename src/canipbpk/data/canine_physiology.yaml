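arterial_blood_fraction: 0.026
bw_reference_kg: 10.5
cardiac_output_ml_min_ref: 1260.0
flow_exponent: 0.75
hematocrit: 0.45
name: canine-reference
organs:
- f_neutral_lipid: 0.003
  f_phospholipid: 0.009
  f_protein: 0.09
  f_water: 0.811
  flow_fraction: 1.0
  name: lung
  volume_fraction: 0.008
- f_neutral_lipid: 0.035
  f_phospholipid: 0.025
  f_protein: 0.13
  f_water: 0.745
  flow_fraction: 0.045
  name: liver
  volume_fraction: 0.033
- f_neutral_lipid: 0.021
  f_phospholipid: 0.016
  f_protein: 0.13
  f_water: 0.783
  flow_fraction: 0.17
  name: kidney
  volume_fraction: 0.0055
- f_neutral_lipid: 0.051
  f_phospholipid: 0.0565
  f_protein: 0.08
  f_water: 0.77
  flow_fraction: 0.02
  name: brain
  volume_fraction: 0.008
- f_neutral_lipid: 0.0115
  f_phospholipid: 0.0166
  f_protein: 0.12
  f_water: 0.779
  flow_fraction: 0.045
  name: heart
  volume_fraction: 0.008
- f_neutral_lipid: 0.0238
  f_phospholipid: 0.0072
  f_protein: 0.17
  f_water: 0.76
  flow_fraction: 0.25
  name: muscle
  volume_fraction: 0.44
- f_neutral_lipid: 0.79
  f_phospholipid: 0.002
  f_protein: 0.025
  f_water: 0.18
  flow_fraction: 0.05
  name: fat
  volume_fraction: 0.15
- f_neutral_lipid: 0.0284
  f_phospholipid: 0.0111
  f_protein: 0.16
  f_water: 0.718
  flow_fraction: 0.06
  name: skin
  volume_fraction: 0.09
- f_neutral_lipid: 0.0487
  f_phospholipid: 0.0163
  f_protein: 0.14
  f_water: 0.718
  flow_fraction: 0.2
  name: gut
  volume_fraction: 0.04
- f_neutral_lipid: 0.0201
  f_phospholipid: 0.0198
  f_protein: 0.12
  f_water: 0.788
  flow_fraction: 0.02
  name: spleen
  volume_fraction: 0.0026
- f_neutral_lipid: 0.074
  f_phospholipid: 0.0011
  f_protein: 0.1
  f_water: 0.439
  flow_fraction: 0.04
  name: bone
  volume_fraction: 0.08
- f_neutral_lipid: 0.0238
  f_phospholipid: 0.0072
  f_protein: 0.17
  f_water: 0.76
  flow_fraction: 0.1
  name: rest
  volume_fraction: 0.05
plasma:
  f_neutral_lipid: 0.0035
  f_phospholipid: 0.00225
  f_protein: 0.07
  f_water: 0.945
venous_blood_fraction: 0.054
version: 1
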