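state,UNTESTED,HPV_INFECTION,CIN1,CIN2,CIN3,CANCER,DEAD
UNTESTED,0.876,0.123,0.000,0.000,0.000,0.000,0.001
HPV_INFECTION,0.300,0.599,0.086,0.014,0.000,0.000,0.001
CIN1,0.135,0.015,0.685,0.149,0.015,0.000,0.001
CIN2,0.120,0.030,0.140,0.659,0.050,0.000,0.001
CIN3,0.000,0.000,0.014,0.026,0.919,0.040,0.001
CANCER,0.000,0.000,0.000,0.000,0.000,0.761,0.239
DEAD,0.000,0.000,0.000,0.000,0.000,0.000,1.000
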