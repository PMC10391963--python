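name,arm,quantity,unit
next_line,intervention,1.0,per_month
next_line,control,1.0,per_month
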