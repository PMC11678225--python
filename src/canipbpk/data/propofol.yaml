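# Propofol substance parameters (2,6-diisopropylphenol).
# Physicochemical values from PubChem CID 4943; lipophilicity, blood:plasma
# ratio, unbound fraction and the unspecific hepatic clearance input are the
# optimized whole-body-model values for the dog. kp_scale is this package's
# global partition calibration factor (1.0 = uncalibrated; see
# drug_model.calibrate_kp_scale).
bp_ratio: 2.36
fu_plasma: 0.02
hepatic_clearance_spec: 47.08
kp_scale: 1.0
logp: 3.49
molecular_weight: 178.27
name: propofol
pka_acid: 11.1
solubility_ref: 0.12
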