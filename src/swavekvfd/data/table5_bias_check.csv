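frequency_hz,mean_mps,se_mps,delta_deg,f_factor,inflation_pct
40,1.380,0.010,13.7,1.007,0.7
60,1.438,0.013,18.6,1.013,1.3
80,1.492,0.007,22.9,1.020,2.0
100,1.507,0.009,26.6,1.028,2.8
120,1.554,0.028,29.9,1.035,3.5
140,1.604,0.016,32.9,1.043,4.3
160,1.684,0.013,35.5,1.050,5.0
180,1.719,0.016,37.8,1.057,5.7
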