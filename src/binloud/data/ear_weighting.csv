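freq_hz,threshold_db_spl
50,44.0
63,38.0
80,32.5
100,27.0
125,22.0
160,18.0
200,14.5
250,11.0
315,8.5
400,7.0
500,6.0
630,5.0
800,4.5
1000,4.0
1250,3.5
1600,2.5
2000,1.0
2500,-1.0
3150,-3.0
4000,-4.0
5000,-2.0
6300,6.9
8000,12.0
10000,17.0
12500,20.0
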