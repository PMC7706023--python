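plaque,mean_capt_oct_mm,mean_capt_ivus_mm,mean_rel_err_pct,min_capt_oct_mm,min_capt_ivus_mm,min_rel_err_pct
1,0.298,0.343,21.37,0.128,0.193,50.78
2,0.273,0.339,39.60,0.092,0.156,69.57
3,0.385,0.398,33.75,0.200,0.183,8.50
4,0.314,0.395,41.35,0.098,0.151,54.08
5,0.368,0.368,33.03,0.141,0.132,6.38
6,0.336,0.361,29.95,0.208,0.177,14.90
7,0.526,0.442,38.00,0.268,0.134,50.00
8,0.533,0.403,40.13,0.291,0.142,51.20
9,0.298,0.401,40.82,0.159,0.247,55.35
10,0.369,0.333,33.97,0.125,0.105,16.00
11,0.343,0.236,44.47,0.177,0.041,76.84
12,0.401,0.241,42.99,0.260,0.023,91.15
13,0.603,0.497,31.28,0.324,0.141,56.48
14,0.593,0.565,27.81,0.339,0.176,48.08
15,0.300,0.348,37.71,0.122,0.025,79.51
16,0.388,0.314,28.78,0.149,0.077,48.32
17,0.283,0.237,25.26,0.127,0.124,2.36
18,0.271,0.271,21.45,0.186,0.125,32.80
19,0.380,0.358,29.50,0.228,0.136,40.35
20,0.373,0.648,73.91,0.249,0.340,36.55
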