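frequency_hz,v1,v2,v3,mean,se
40,1.360,1.390,1.390,1.380,0.010
60,1.413,1.444,1.458,1.438,0.013
80,1.479,1.497,1.501,1.492,0.007
100,1.492,1.505,1.523,1.507,0.009
120,1.513,1.541,1.608,1.554,0.028
140,1.577,1.603,1.632,1.604,0.016
160,1.660,1.688,1.705,1.684,0.013
180,1.694,1.714,1.750,1.719,0.016
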