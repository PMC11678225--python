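# The nine literature study designs used to develop and evaluate the canine
# propofol model, with each study's model-predicted and observed AUClast
# (µg·h/mL). Doses are mg/kg (bolus) and mg/kg/min (infusion); durations are
# minutes; body weights kg. extra_infusions entries are
# [rate_mg_kg_min, start_min_after_bolus_start, duration_min] for staged
# infusion designs.
studies:
- study_id: cockshott_1992
  label: Cockshott et al. (1992)
  bolus_dose: 7.0
  infusion_rate: 0.47
  infusion_duration_min: 360.0
  body_weight: 17.9
  n_animals: 3
  role: development
  predicted_auclast: 85.63
  observed_auclast: 80.53
- study_id: nolan_reid_1993
  label: Nolan and Reid (1993)
  bolus_dose: 4.0
  infusion_rate: 0.4
  infusion_duration_min: 60.0
  body_weight: 21.25
  n_animals: 7
  role: development
  predicted_auclast: 13.81
  observed_auclast: 12.04
- study_id: luiz_2012
  label: Luiz (2012)
  bolus_dose: 8.0
  infusion_rate: 0.4
  infusion_duration_min: 60.0
  body_weight: 10.7
  n_animals: 6
  role: development
  predicted_auclast: 14.05
  observed_auclast: 14.61
- study_id: reid_nolan_1996
  label: Reid and Nolan (1996)
  bolus_dose: 5.0
  infusion_rate: 0.0
  infusion_duration_min: 0.0
  body_weight: 29.0
  n_animals: 6
  role: development
  predicted_auclast: 2.25
  observed_auclast: 2.86
- study_id: hall_1994
  label: Hall et al. (1994)
  bolus_dose: 6.9
  infusion_rate: 0.4
  infusion_duration_min: 120.0
  body_weight: 21.5
  n_animals: 6
  role: validation
  predicted_auclast: 26.93
  observed_auclast: 26.07
- study_id: hughes_nolan_1999
  label: Hughes and Nolan (1999)
  bolus_dose: 4.0
  infusion_rate: 0.3
  infusion_duration_min: 20.0
  extra_infusions:
  - [0.2, 21.0, 70.0]
  body_weight: 25.58
  n_animals: 8
  role: validation
  predicted_auclast: 10.92
  observed_auclast: 8.87
- study_id: nolan_reid_grant_1993
  label: Nolan, Reid and Grant (1993)
  bolus_dose: 6.5
  infusion_rate: 0.0
  infusion_duration_min: 0.0
  body_weight: 29.5
  n_animals: 6
  role: validation
  predicted_auclast: 2.92
  observed_auclast: 1.56
- study_id: zoran_1993
  label: Zoran et al. (1993)
  bolus_dose: 5.0
  infusion_rate: 0.0
  infusion_duration_min: 0.0
  body_weight: 32.7
  n_animals: 10
  role: validation
  predicted_auclast: 2.19
  observed_auclast: 1.51
- study_id: mandsager_1995
  label: Mandsager et al. (1995)
  bolus_dose: 10.0
  infusion_rate: 0.4
  infusion_duration_min: 120.0
  body_weight: 25.5
  n_animals: 5
  role: validation
  predicted_auclast: 25.89
  observed_auclast: 23.93
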