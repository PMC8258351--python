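freq_hz,rel_level_db
63,35.0
80,38.0
100,41.0
125,44.0
160,49.0
200,52.0
250,55.0
315,56.0
400,57.0
500,56.5
630,54.0
800,52.0
1000,50.0
1250,49.0
1600,48.0
2000,47.0
2500,46.0
3150,45.0
4000,44.0
5000,43.0
6300,42.0
8000,41.0
10000,40.0
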