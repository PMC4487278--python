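energy_keV,mu_rho,mu_tr_rho
5.000,39.2758,38.3395
5.500,29.5814,28.7757
6.000,22.8373,22.1446
6.500,17.9874,17.3535
7.000,14.421,13.8475
7.500,11.7399,11.2237
8.000,9.68535,9.22163
8.500,8.09409,7.64892
9.000,6.83432,6.41288
9.500,5.8239,5.42831
10.000,5.004,4.63456
10.500,4.35647,3.97995
11.000,3.81744,3.44225
11.500,3.36495,2.9966
12.000,2.98222,2.62422
12.500,2.65621,2.31071
13.000,2.37672,2.04494
13.500,2.1357,1.81819
14.000,1.9267,1.6236
14.500,1.74454,1.45569
15.000,1.58503,1.31005
15.500,1.45931,1.18212
16.000,1.34714,1.0702
16.500,1.24672,0.971895
17.000,1.15649,0.885196
17.500,1.07518,0.808451
18.000,1.00169,0.740279
18.500,0.935066,0.679522
19.000,0.874515,0.625204
19.500,0.819343,0.576498
20.000,0.768953,0.532702
20.500,0.73318,0.493688
21.000,0.69988,0.458375
21.500,0.66883,0.426335
22.000,0.639829,0.397199
22.500,0.6127,0.370646
23.000,0.587285,0.346397
23.500,0.563441,0.324209
24.000,0.541042,0.303867
24.500,0.519971,0.285184
25.000,0.500125,0.267995
25.500,0.481411,0.252154
26.000,0.463743,0.237532
26.500,0.447045,0.224014
27.000,0.431247,0.211498
27.500,0.416284,0.199893
28.000,0.402098,0.189118
28.500,0.388637,0.179101
29.000,0.375851,0.169776
29.500,0.363696,0.161085
30.000,0.35213,0.152975
30.500,0.345091,0.146028
31.000,0.338305,0.139503
31.500,0.331757,0.133367
32.000,0.325437,0.127592
32.500,0.319332,0.12215
33.000,0.313433,0.117018
33.500,0.307729,0.112174
34.000,0.302211,0.107599
34.500,0.29687,0.103272
35.000,0.291699,0.0991786
35.500,0.28669,0.0953018
36.000,0.281835,0.0916277
36.500,0.277128,0.088143
37.000,0.272562,0.0848356
37.500,0.26813,0.0816944
38.000,0.263829,0.0787087
38.500,0.259651,0.0758692
39.000,0.255592,0.0731668
39.500,0.251648,0.0705932
40.000,0.247812,0.068141
40.500,0.245385,0.0662328
41.000,0.24301,0.0644005
41.500,0.240687,0.0626401
42.000,0.238414,0.0609482
42.500,0.236188,0.0593212
43.000,0.234009,0.0577558
43.500,0.231875,0.0562492
44.000,0.229785,0.0547985
44.500,0.227736,0.0534009
45.000,0.225729,0.052054
45.500,0.223761,0.0507554
46.000,0.221832,0.0495029
46.500,0.21994,0.0482944
47.000,0.218084,0.0471278
47.500,0.216263,0.0460013
48.000,0.214476,0.0449131
48.500,0.212722,0.0438615
49.000,0.211,0.042845
49.500,0.20931,0.0418619
50.000,0.20765,0.040911
50.500,0.206485,0.0402519
51.000,0.205338,0.0396096
51.500,0.204209,0.0389838
52.000,0.203096,0.0383737
52.500,0.202,0.0377789
53.000,0.200921,0.0371988
53.500,0.199857,0.036633
54.000,0.198808,0.0360809
54.500,0.197775,0.0355421
55.000,0.196757,0.0350162
55.500,0.195753,0.0345027
56.000,0.194763,0.0340012
56.500,0.193786,0.0335114
57.000,0.192823,0.0330328
57.500,0.191874,0.0325652
58.000,0.190937,0.0321082
58.500,0.190013,0.0316614
59.000,0.189101,0.0312246
59.500,0.188201,0.0307974
60.000,0.187312,0.0303796
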