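parameter,low,high
discount_rate,0.0,0.06
hr_os,0.35,1.0499999999999998
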