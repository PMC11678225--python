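# Propofol therapeutic plasma-concentration reference values for dogs
# (µg/mL), from the clinical target-controlled-infusion literature:
# 2.5-4.7 maintenance window, 3.0 induction target, 2.15 anesthetic-recovery
# threshold, 6.5 adverse-effect (apnea/muscle spasm) threshold.
adverse_threshold: 6.5
induction_target: 3.0
lower: 2.5
recovery_threshold: 2.15
upper: 4.7
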