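# Study-calibration aggregates for the three screening arms of the trial:
# 3086 women aged 35-65 recruited, participation 0.979 (3021 screened).
# Counts: screened, initial screen positives, referred to colposcopy
# (intention, before loss to follow-up), lost to follow-up, confirmed
# positives by pathology grade.  reference_dalys are the per-arm DALYs
# averted reported by the original study (life-table- and age-dependent;
# not reproducible from the printed inputs, used as CUR denominators in
# the study profile).
n_recruited: 3086
participation: 0.979
start_age: 45
horizon: 15
arms:
  - name: VIA_VILI
    n_screened: 1008
    n_initial_positive: 133
    n_referred: 133
    n_lost_followup: 2
    case_mix: {CIN1: 8, CIN2: 3, CIN3: 3}
    reference_dalys: 50.624
  - name: TCT
    n_screened: 1012
    n_initial_positive: 43
    n_referred: 43
    n_lost_followup: 12
    case_mix: {CIN1: 2, CIN3: 1}
    reference_dalys: 17.603
  - name: HPV
    n_screened: 1001
    n_initial_positive: 146
    n_referred: 53
    n_lost_followup: 13
    case_mix: {CIN1: 2, CIN2: 1, CIN3: 3, CANCER: 1}
    reference_dalys: 42.301
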