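parameter,mean,se
error_rate_gain,0.09,0.03
error_rate_loss,0.24,0.04
rt_gain_over_rt_loss,0.70,0.04
rtc_over_rtw_gain,0.82,0.10
rtc_over_rtw_loss,0.93,0.06
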