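energy_keV,mu_rho,mu_tr_rho
5.000,41.5294,40.8466
5.500,31.2043,30.5687
6.000,24.0379,23.4623
6.500,18.8967,18.3387
7.000,15.1231,14.5987
7.500,12.2911,11.8063
8.000,10.1245,9.68025
8.500,8.45144,8.01476
9.000,7.12841,6.70814
9.500,6.06839,5.66909
10.000,5.2091,4.83276
10.500,4.5329,4.14417
11.000,3.97027,3.57938
11.500,3.49819,3.11191
12.000,3.09906,2.72181
12.500,2.75923,2.39378
13.000,2.46801,2.11604
13.500,2.21697,1.87935
14.000,1.99936,1.67645
14.500,1.80977,1.50155
15.000,1.6438,1.35002
15.500,1.51417,1.21703
16.000,1.39846,1.1008
16.500,1.29482,0.9988
17.000,1.20166,0.908922
17.500,1.11768,0.829433
18.000,1.04173,0.758882
18.500,0.972857,0.696055
19.000,0.910238,0.639931
19.500,0.853161,0.589645
20.000,0.80101,0.544461
20.500,0.764675,0.504344
21.000,0.73081,0.468048
21.500,0.699196,0.435132
22.000,0.669635,0.405213
22.500,0.641951,0.377958
23.000,0.615988,0.353079
23.500,0.591604,0.330324
24.000,0.568672,0.30947
24.500,0.547079,0.290326
25.000,0.526721,0.272719
25.500,0.507504,0.256499
26.000,0.489345,0.241533
26.500,0.472166,0.227702
27.000,0.455898,0.214901
27.500,0.440476,0.203036
28.000,0.425842,0.192024
28.500,0.411943,0.181789
29.000,0.398729,0.172265
29.500,0.386157,0.163392
30.000,0.374185,0.155113
30.500,0.367054,0.148098
31.000,0.360172,0.141507
31.500,0.353526,0.135307
32.000,0.347105,0.129471
32.500,0.340897,0.123971
33.000,0.334893,0.118783
33.500,0.329083,0.113886
34.000,0.323457,0.109259
34.500,0.318007,0.104883
35.000,0.312726,0.100742
35.500,0.307606,0.0968194
36.000,0.30264,0.0931015
36.500,0.29782,0.0895748
37.000,0.293142,0.0862269
37.500,0.288598,0.0830467
38.000,0.284184,0.0800236
38.500,0.279894,0.0771479
39.000,0.275722,0.0744107
39.500,0.271665,0.0718037
40.000,0.267717,0.0693192
40.500,0.265244,0.0674278
41.000,0.262823,0.0656104
41.500,0.260453,0.0638631
42.000,0.258133,0.0621824
42.500,0.25586,0.060565
43.000,0.253633,0.059008
43.500,0.251452,0.0575082
44.000,0.249314,0.0560631
44.500,0.247218,0.05467
45.000,0.245162,0.0533266
45.500,0.243146,0.0520304
46.000,0.241169,0.0507795
46.500,0.239229,0.0495716
47.000,0.237324,0.0484049
47.500,0.235455,0.0472776
48.000,0.23362,0.046188
48.500,0.231819,0.0451344
49.000,0.230049,0.0441153
49.500,0.22831,0.0431291
50.000,0.226602,0.0421746
50.500,0.225412,0.0415352
51.000,0.224239,0.0409116
51.500,0.223084,0.0403033
52.000,0.221946,0.0397099
52.500,0.220824,0.0391307
53.000,0.219719,0.0385653
53.500,0.218629,0.0380133
54.000,0.217555,0.0374743
54.500,0.216496,0.0369477
55.000,0.215452,0.0364332
55.500,0.214422,0.0359305
56.000,0.213406,0.0354391
56.500,0.212404,0.0349588
57.000,0.211416,0.034489
57.500,0.210441,0.0340297
58.000,0.209478,0.0335803
58.500,0.208529,0.0331406
59.000,0.207591,0.0327104
59.500,0.206666,0.0322893
60.000,0.205753,0.0318771
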