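name,arm,quantity,unit,phase_start,phase_end,phase_unit,txcycle_length_weeks,cap
drug_intervention,intervention,1.0,per_month,1.0,,month,,
drug_control,control,1.0,per_month,1.0,,month,,
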