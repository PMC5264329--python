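# GBD-style DALY constants: gamma = social discount rate, beta =
# age-weighting exponent, C = age-weighting correction constant (study
# value; the common GBD constant is 0.16243).  Disability weights per
# health state; DEAD carries weight 1 by convention for YLL.
gamma: 0.03
beta: 0.04
C: 0.1658
disability_weights:
  UNTESTED: 0.0
  HPV_INFECTION: 0.0
  CIN1: 0.0
  CIN2: 0.1238
  CIN3: 0.1941
  CANCER: 0.307
  DEAD: 1.0
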