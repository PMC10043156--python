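bmi_category,factor,level,median_log,exp_median,posterior_sd,hdi_low,hdi_high,ess
underweight,age_band,<=25,0.023,1.023,0.003,0.018,0.028,16600
underweight,age_band,26-34,0.008,1.008,0.002,0.004,0.012,15355
underweight,height_band,<=155,-0.009,0.991,0.002,-0.013,-0.005,16741
underweight,height_band,156-161,-0.007,0.993,0.002,-0.010,-0.003,16165
underweight,parity,primipara,-0.001,0.999,0.002,-0.004,0.002,16262
underweight,smoking,quit_before,0.020,1.020,0.002,0.016,0.023,15647
underweight,smoking,quit_after,0.070,1.073,0.002,0.066,0.075,16324
underweight,smoking,during,0.060,1.062,0.004,0.054,0.067,16696
underweight,previous_disease,yes,-0.003,0.997,0.002,-0.006,0.001,17192
underweight,sd_intercept,,0.080,,0.001,0.078,0.081,22310
normal,age_band,<=25,0.015,1.015,0.001,0.012,0.018,5691
normal,age_band,26-34,0.004,1.004,0.001,0.002,0.006,6267
normal,height_band,<=155,-0.014,0.986,0.001,-0.016,-0.012,5972
normal,height_band,156-161,-0.006,0.994,0.001,-0.008,-0.004,6203
normal,parity,primipara,0.006,1.006,0.001,0.004,0.007,6822
normal,smoking,quit_before,0.014,1.014,0.001,0.012,0.016,5886
normal,smoking,quit_after,0.063,1.065,0.001,0.060,0.065,6070
normal,smoking,during,0.050,1.051,0.002,0.046,0.054,5948
normal,previous_disease,yes,-0.005,0.995,0.001,-0.007,-0.004,6096
normal,sd_intercept,,0.094,,0.000,0.093,0.094,7472
overweight,age_band,<=25,-0.013,0.987,0.006,-0.024,-0.001,14206
overweight,age_band,26-34,-0.015,0.985,0.006,-0.027,-0.003,14730
overweight,height_band,<=155,0.003,1.003,0.004,-0.006,0.011,13474
overweight,height_band,156-161,0.002,1.002,0.005,-0.008,0.012,14028
overweight,parity,primipara,0.014,1.014,0.004,0.007,0.022,14541
overweight,smoking,quit_before,0.013,1.013,0.004,0.004,0.021,15314
overweight,smoking,quit_after,0.053,1.054,0.005,0.042,0.063,13883
overweight,smoking,during,0.025,1.025,0.008,0.010,0.040,14891
overweight,previous_disease,yes,-0.014,0.986,0.004,-0.021,-0.006,13889
overweight,sd_intercept,,0.137,,0.001,0.135,0.140,21714
obese,age_band,<=25,-0.020,0.980,0.014,-0.047,0.007,15617
obese,age_band,26-34,-0.015,0.985,0.015,-0.044,0.014,15261
obese,height_band,<=155,-0.002,0.998,0.010,-0.021,0.018,15241
obese,height_band,156-161,-0.010,0.990,0.011,-0.032,0.013,15696
obese,parity,primipara,0.024,1.024,0.009,0.006,0.042,14211
obese,smoking,quit_before,-0.030,0.970,0.010,-0.050,-0.011,15733
obese,smoking,quit_after,0.042,1.043,0.012,0.019,0.064,15576
obese,smoking,during,0.034,1.035,0.017,0.001,0.067,16429
obese,previous_disease,yes,-0.013,0.987,0.009,-0.030,0.004,15303
obese,sd_intercept,,0.174,,0.003,0.168,0.180,16658
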