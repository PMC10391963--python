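name,unit_cost,dsa_low,dsa_high
drug_intervention,2000.0,,
drug_control,1500.0,,
next_line,0.0,,
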