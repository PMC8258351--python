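freq_hz,ild_db
63,0.5
125,1.0
250,1.5
500,2.5
1000,4.0
1600,6.0
2000,8.0
3150,10.0
4000,11.0
6300,12.0
8000,12.0
10000,12.0
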