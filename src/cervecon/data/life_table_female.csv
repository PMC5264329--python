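age,residual_expectancy
0,82.50
1,81.84
5,77.95
10,72.99
15,68.02
20,63.08
25,58.17
30,53.27
35,48.38
40,43.53
45,38.72
50,33.99
55,29.37
60,24.83
65,20.44
70,16.20
75,12.28
80,8.90
85,6.22
90,4.25
95,2.89
100,1.91
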