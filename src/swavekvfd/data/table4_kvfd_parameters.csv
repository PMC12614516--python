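phantom,method,e0_kpa,eta_kpa_s_alpha,alpha
hard,rheometer,5.49,7.64,0.12
hard,tof,5.37,0.012,0.86
soft,rheometer,1.33,4.24,0.11
soft,tof,1.152,0.0363,0.42
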