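age_lo	age_hi	prior
40	50	0.002
50	55	0.004
55	60	0.0075
60	65	0.0125
65	70	0.02
70	75	0.025
75	80	0.035
80	120	0.04
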