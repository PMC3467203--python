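age,annual_mortality_probability
65,0.013000
66,0.014253
67,0.015626
68,0.017132
69,0.018783
70,0.020593
71,0.022577
72,0.024753
73,0.027138
74,0.029754
75,0.032621
76,0.035764
77,0.039211
78,0.042989
79,0.047132
80,0.051674
81,0.056653
82,0.062113
83,0.068098
84,0.074660
85,0.081855
86,0.089743
87,0.098391
88,0.107872
89,0.118268
90,0.129664
91,0.142159
92,0.155859
93,0.170878
94,0.187345
95,0.205398
96,0.225191
97,0.246892
98,0.270683
99,0.296768
100,0.325366
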