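parameter,green,green_se,blue,blue_se,orange,orange_se
size,27,0,26,0,91,0
error_rate,0.09,0.01,0.11,0.01,0.34,0.01
rt_6535_sec,0.61,0.04,0.79,0.05,0.67,0.02
rt_6535_over_rt_5050,0.81,0.02,1.28,0.06,0.99,0.02
rtc_over_rtw_6535,0.93,0.05,0.91,0.06,0.98,0.02
gaba_6535,1.02,0.03,1.13,0.05,1.03,0.02
gaba_5050,1.06,0.04,1.09,0.05,1.03,0.02
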