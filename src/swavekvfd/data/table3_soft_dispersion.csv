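frequency_hz,v1,v2,v3,v4,v5,mean,se
40,0.686,0.691,0.700,0.705,0.711,0.698,0.004
60,0.699,0.709,0.716,0.725,0.727,0.715,0.005
80,0.713,0.724,0.732,0.736,0.744,0.730,0.005
100,0.731,0.733,0.737,0.745,0.761,0.741,0.005
120,0.736,0.739,0.747,0.758,0.763,0.749,0.005
140,0.746,0.745,0.751,0.759,0.767,0.754,0.004
160,0.747,0.754,0.762,0.770,0.778,0.762,0.006
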