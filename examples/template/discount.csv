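annual_rate,horizon_months,dist_pfs,dist_os
0.03,60,weibull,weibull
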