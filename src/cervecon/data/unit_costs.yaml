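# Unit-cost schedule for the study calibration (2014 RMB).
# Surgery tariffs are the government-specified direct treatment costs per
# confirmed lesion grade; radiochemo is the radiotherapy+chemotherapy cost
# per cervical-cancer case; per-diem social rates come from the local
# statistical yearbook; stay_days are hospital mean lengths of stay.
surgery_cost:
  CIN2: 2400.0
  CIN3: 5650.0
  CANCER: 8500.0
radiochemo_cost: 54823.3
per_diem:
  diet: 8.5
  accommodation: 3.7
  transport_comm: 2.8
  wage: 93.8
stay_days:
  CIN1: 5.8
  CIN2: 7.5
  CIN3: 12.3
  CANCER: 26.3
# Companion multipliers: a patient travels with one companion, so two
# persons eat and two daily wages are lost per hospital day, while lodging
# and transport/communication are counted once per day.
companion:
  diet_persons: 2
  wage_persons: 2
discount_rate: 0.03
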