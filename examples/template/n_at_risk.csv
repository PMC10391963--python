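endpoint,arm,time,n_at_risk
OS,control,0.0,300
OS,control,6.0,253
OS,control,12.0,194
OS,control,18.0,154
OS,control,24.0,113
OS,control,30.0,89
OS,control,36.0,70
PFS,control,0.0,300
PFS,control,6.0,134
PFS,control,12.0,53
PFS,control,18.0,28
PFS,control,24.0,8
PFS,control,30.0,3
PFS,control,36.0,1
OS,intervention,0.0,300
OS,intervention,6.0,261
OS,intervention,12.0,217
OS,intervention,18.0,184
OS,intervention,24.0,149
OS,intervention,30.0,124
OS,intervention,36.0,99
PFS,intervention,0.0,300
PFS,intervention,6.0,190
PFS,intervention,12.0,117
PFS,intervention,18.0,63
PFS,intervention,24.0,38
PFS,intervention,30.0,21
PFS,intervention,36.0,7
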