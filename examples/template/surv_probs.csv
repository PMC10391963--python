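endpoint,arm,time,surv_prob
OS,control,0.0,1.0
OS,control,1.0,0.9933333333333334
OS,control,2.0,0.9600000000000001
OS,control,3.0,0.9266666666666667
OS,control,4.0,0.8966666666666667
OS,control,5.0,0.8833333333333334
OS,control,6.0,0.8433333333333336
OS,control,7.0,0.806666666666667
OS,control,8.0,0.7633333333333341
OS,control,9.0,0.7333333333333342
OS,control,10.0,0.7133333333333344
OS,control,11.0,0.6833333333333343
OS,control,12.0,0.6466666666666679
OS,control,13.0,0.6233333333333345
OS,control,14.0,0.6066666666666679
OS,control,15.0,0.5733333333333345
OS,control,16.0,0.5466666666666677
OS,control,17.0,0.5333333333333344
OS,control,18.0,0.5133333333333345
OS,control,19.0,0.49000000000000116
OS,control,20.0,0.460000000000001
OS,control,21.0,0.4333333333333342
OS,control,22.0,0.4100000000000007
OS,control,23.0,0.40000000000000063
OS,control,24.0,0.37666666666666737
OS,control,25.0,0.37000000000000066
OS,control,26.0,0.3666666666666673
OS,control,27.0,0.35000000000000064
OS,control,28.0,0.32333333333333386
OS,control,29.0,0.31000000000000055
OS,control,30.0,0.2966666666666672
OS,control,31.0,0.2866666666666671
OS,control,32.0,0.2766666666666671
OS,control,33.0,0.2600000000000004
OS,control,34.0,0.24666666666666706
OS,control,35.0,0.24333333333333373
OS,control,36.0,0.23333333333333373
PFS,control,0.0,1.0
PFS,control,1.0,0.92
PFS,control,2.0,0.8133333333333336
PFS,control,3.0,0.6966666666666677
PFS,control,4.0,0.6166666666666679
PFS,control,5.0,0.5333333333333344
PFS,control,6.0,0.4466666666666676
PFS,control,7.0,0.3866666666666673
PFS,control,8.0,0.32000000000000056
PFS,control,9.0,0.27333333333333376
PFS,control,10.0,0.24666666666666706
PFS,control,11.0,0.21666666666666706
PFS,control,12.0,0.176666666666667
PFS,control,13.0,0.1566666666666669
PFS,control,14.0,0.14666666666666686
PFS,control,15.0,0.13666666666666683
PFS,control,16.0,0.12000000000000018
PFS,control,17.0,0.11000000000000015
PFS,control,18.0,0.09333333333333346
PFS,control,19.0,0.07333333333333343
PFS,control,20.0,0.06333333333333341
PFS,control,21.0,0.05333333333333339
PFS,control,22.0,0.040000000000000056
PFS,control,23.0,0.0266666666666667
PFS,control,24.0,0.0266666666666667
PFS,control,25.0,0.0266666666666667
PFS,control,26.0,0.020000000000000025
PFS,control,27.0,0.016666666666666687
PFS,control,28.0,0.01333333333333335
PFS,control,29.0,0.010000000000000012
PFS,control,30.0,0.010000000000000012
PFS,control,31.0,0.010000000000000012
PFS,control,32.0,0.006666666666666676
PFS,control,33.0,0.003333333333333338
PFS,control,34.0,0.003333333333333338
PFS,control,35.0,0.003333333333333338
PFS,control,36.0,0.003333333333333338
OS,intervention,0.0,1.0
OS,intervention,1.0,0.9800000000000001
OS,intervention,2.0,0.9600000000000001
OS,intervention,3.0,0.9400000000000001
OS,intervention,4.0,0.9300000000000002
OS,intervention,5.0,0.9033333333333333
OS,intervention,6.0,0.8700000000000001
OS,intervention,7.0,0.8300000000000004
OS,intervention,8.0,0.8200000000000003
OS,intervention,9.0,0.806666666666667
OS,intervention,10.0,0.773333333333334
OS,intervention,11.0,0.7533333333333341
OS,intervention,12.0,0.7233333333333343
OS,intervention,13.0,0.6933333333333342
OS,intervention,14.0,0.6733333333333344
OS,intervention,15.0,0.6466666666666679
OS,intervention,16.0,0.6333333333333346
OS,intervention,17.0,0.6300000000000013
OS,intervention,18.0,0.6133333333333346
OS,intervention,19.0,0.5766666666666679
OS,intervention,20.0,0.5633333333333346
OS,intervention,21.0,0.5400000000000011
OS,intervention,22.0,0.5333333333333344
OS,intervention,23.0,0.5100000000000012
OS,intervention,24.0,0.49666666666666787
OS,intervention,25.0,0.4866666666666678
OS,intervention,26.0,0.47000000000000103
OS,intervention,27.0,0.45666666666666766
OS,intervention,28.0,0.44333333333333425
OS,intervention,29.0,0.4333333333333342
OS,intervention,30.0,0.41333333333333405
OS,intervention,31.0,0.3900000000000006
OS,intervention,32.0,0.373333333333334
OS,intervention,33.0,0.3666666666666673
OS,intervention,34.0,0.35666666666666735
OS,intervention,35.0,0.34333333333333393
OS,intervention,36.0,0.3300000000000005
PFS,intervention,0.0,1.0
PFS,intervention,1.0,0.9333333333333335
PFS,intervention,2.0,0.8700000000000001
PFS,intervention,3.0,0.8200000000000003
PFS,intervention,4.0,0.7600000000000008
PFS,intervention,5.0,0.7033333333333344
PFS,intervention,6.0,0.6333333333333346
PFS,intervention,7.0,0.5633333333333346
PFS,intervention,8.0,0.5400000000000011
PFS,intervention,9.0,0.49000000000000116
PFS,intervention,10.0,0.4466666666666676
PFS,intervention,11.0,0.4300000000000008
PFS,intervention,12.0,0.3900000000000006
PFS,intervention,13.0,0.34333333333333393
PFS,intervention,14.0,0.3166666666666672
PFS,intervention,15.0,0.29333333333333383
PFS,intervention,16.0,0.26333333333333375
PFS,intervention,17.0,0.24000000000000038
PFS,intervention,18.0,0.2100000000000004
PFS,intervention,19.0,0.186666666666667
PFS,intervention,20.0,0.17333333333333367
PFS,intervention,21.0,0.15333333333333354
PFS,intervention,22.0,0.15000000000000022
PFS,intervention,23.0,0.13666666666666683
PFS,intervention,24.0,0.12666666666666684
PFS,intervention,25.0,0.11666666666666684
PFS,intervention,26.0,0.09666666666666679
PFS,intervention,27.0,0.09666666666666679
PFS,intervention,28.0,0.0866666666666668
PFS,intervention,29.0,0.07333333333333343
PFS,intervention,30.0,0.07000000000000009
PFS,intervention,31.0,0.05666666666666673
PFS,intervention,32.0,0.05333333333333339
PFS,intervention,33.0,0.05000000000000006
PFS,intervention,34.0,0.040000000000000056
PFS,intervention,35.0,0.033333333333333375
PFS,intervention,36.0,0.023333333333333362
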