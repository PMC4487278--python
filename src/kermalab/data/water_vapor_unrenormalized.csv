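energy_keV,mu_rho,mu_tr_rho
5.000,42.58,41.88
5.500,31.9902,31.3385
6.000,24.64,24.05
6.500,19.367,18.7951
7.000,15.4967,14.9594
7.500,12.5921,12.0955
8.000,10.37,9.915
8.500,8.65418,8.20703
9.000,7.29733,6.8671
9.500,6.21023,5.8016
10.000,5.329,4.944
10.500,4.63555,4.23802
11.000,4.05857,3.65899
11.500,3.57448,3.17977
12.000,3.16519,2.77988
12.500,2.81671,2.44365
13.000,2.5181,2.15898
13.500,2.26068,1.91641
14.000,2.03756,1.70848
14.500,1.84317,1.52926
15.000,1.673,1.374
15.500,1.54016,1.23792
16.000,1.4216,1.11902
16.500,1.31541,1.01468
17.000,1.21997,0.92277
17.500,1.13393,0.841496
18.000,1.05613,0.769376
18.500,0.98559,0.705165
19.000,0.921456,0.647818
19.500,0.863003,0.596447
20.000,0.8096,0.5503
20.500,0.772605,0.509574
21.000,0.738133,0.472738
21.500,0.705956,0.439339
22.000,0.675875,0.408989
22.500,0.647708,0.381348
23.000,0.621297,0.356122
23.500,0.596496,0.333055
24.000,0.573177,0.311922
24.500,0.551222,0.292525
25.000,0.530527,0.27469
25.500,0.510996,0.258264
26.000,0.492542,0.243111
26.500,0.475088,0.229111
27.000,0.458561,0.216156
27.500,0.442897,0.204152
28.000,0.428036,0.193014
28.500,0.413924,0.182664
29.000,0.40051,0.173035
29.500,0.38775,0.164065
30.000,0.3756,0.1557
30.500,0.36841,0.148645
31.000,0.36147,0.142017
31.500,0.35477,0.135783
32.000,0.348296,0.129915
32.500,0.342038,0.124386
33.000,0.335985,0.119171
33.500,0.330129,0.114248
34.000,0.324458,0.109597
34.500,0.318966,0.105199
35.000,0.313644,0.101037
35.500,0.308484,0.0970959
36.000,0.30348,0.09336
36.500,0.298624,0.0898165
37.000,0.29391,0.086453
37.500,0.289333,0.0832581
38.000,0.284886,0.0802212
38.500,0.280564,0.0773327
39.000,0.276362,0.0745835
39.500,0.272276,0.0719652
40.000,0.2683,0.06947
40.500,0.265808,0.0675714
41.000,0.26337,0.065747
41.500,0.260983,0.063993
42.000,0.258646,0.0623061
42.500,0.256357,0.0606828
43.000,0.254115,0.05912
43.500,0.251918,0.0576149
44.000,0.249765,0.0561646
44.500,0.247654,0.0547667
45.000,0.245585,0.0534185
45.500,0.243555,0.0521179
46.000,0.241564,0.0508627
46.500,0.239611,0.0496508
47.000,0.237694,0.0484802
47.500,0.235812,0.0473492
48.000,0.233965,0.046256
48.500,0.232151,0.045199
49.000,0.230369,0.0441767
49.500,0.228619,0.0431875
50.000,0.2269,0.04223
50.500,0.225701,0.0415884
51.000,0.224519,0.0409627
51.500,0.223355,0.0403524
52.000,0.222209,0.039757
52.500,0.221079,0.0391759
53.000,0.219966,0.0386087
53.500,0.218868,0.0380549
54.000,0.217786,0.0375141
54.500,0.21672,0.0369859
55.000,0.215668,0.0364698
55.500,0.214631,0.0359655
56.000,0.213608,0.0354726
56.500,0.212599,0.0349907
57.000,0.211603,0.0345196
57.500,0.210621,0.0340588
58.000,0.209652,0.0336081
58.500,0.208696,0.0331672
59.000,0.207752,0.0327357
59.500,0.20682,0.0323134
60.000,0.2059,0.0319
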