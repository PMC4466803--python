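group,n,ker_bottom_mean,ker_bottom_sd,ker_top_mean,ker_top_sd,depth_mean,depth_sd,width_mean,width_sd
crush,3,0.095,0.015,0.023,0.005,0.22,0.03,0.406,0.010
probe_and_base,3,0.067,0.007,0.0205,0.0013,0.161,0.013,0.35,0.02
probe,2,0.029,0.005,0.018,0.007,0.120,0.006,0.304,0.003
tip,5,0.08,0.03,0.035,0.011,0.22,0.05,0.44,0.07
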