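energy_keV,mu_rho,mu_tr_rho
5.000,40.27,39.31
5.500,30.327,29.501
6.000,23.41,22.7
6.500,18.4359,17.7861
7.000,14.778,14.1903
7.500,12.0282,11.4993
8.000,9.921,9.446
8.500,8.28904,7.83315
9.000,6.99707,6.56559
9.500,5.96084,5.55594
10.000,5.12,4.742
10.500,4.45595,4.07082
11.000,3.90316,3.51955
11.500,3.43915,3.06268
12.000,3.04667,2.68093
12.500,2.71236,2.35956
13.000,2.42578,2.08714
13.500,2.17863,1.85474
14.000,1.96433,1.65531
14.500,1.77756,1.48323
15.000,1.614,1.334
15.500,1.48516,1.20306
16.000,1.37023,1.08854
16.500,1.26732,0.987959
17.000,1.17488,0.899269
17.500,1.09158,0.820776
18.000,1.01628,0.751065
18.500,0.948036,0.688948
19.000,0.886014,0.633425
19.500,0.829507,0.583649
20.000,0.7779,0.5389
20.500,0.741457,0.499261
21.000,0.707539,0.463391
21.500,0.675917,0.430853
22.000,0.646387,0.401271
22.500,0.618769,0.374317
23.000,0.592899,0.349709
23.500,0.568633,0.327196
24.000,0.54584,0.306562
24.500,0.524403,0.287615
25.000,0.504216,0.270187
25.500,0.485182,0.254129
26.000,0.467217,0.239311
26.500,0.45024,0.225614
27.000,0.43418,0.212936
27.500,0.418972,0.201184
28.000,0.404557,0.190275
28.500,0.39088,0.180135
29.000,0.377891,0.170698
29.500,0.365545,0.161904
30.000,0.3538,0.1537
30.500,0.346691,0.146705
31.000,0.339836,0.140135
31.500,0.333224,0.133957
32.000,0.326841,0.128142
32.500,0.320677,0.122664
33.000,0.314721,0.117499
33.500,0.308962,0.112624
34.000,0.303392,0.108019
34.500,0.298001,0.103666
35.000,0.292781,0.0995465
35.500,0.287726,0.095646
36.000,0.282826,0.0919498
36.500,0.278075,0.0884444
37.000,0.273468,0.0851177
37.500,0.268997,0.0819583
38.000,0.264657,0.0789557
38.500,0.260442,0.0761003
39.000,0.256348,0.0733829
39.500,0.252368,0.0707954
40.000,0.2485,0.06833
40.500,0.246051,0.0664126
41.000,0.243656,0.0645715
41.500,0.241312,0.0628029
42.000,0.239019,0.061103
42.500,0.236775,0.0594685
43.000,0.234577,0.057896
43.500,0.232425,0.0563826
44.000,0.230317,0.0549253
44.500,0.228251,0.0535216
45.000,0.226227,0.0521688
45.500,0.224243,0.0508646
46.000,0.222297,0.0496068
46.500,0.220389,0.0483931
47.000,0.218518,0.0472217
47.500,0.216682,0.0460905
48.000,0.214881,0.0449979
48.500,0.213113,0.0439421
49.000,0.211377,0.0429215
49.500,0.209673,0.0419346
50.000,0.208,0.04098
50.500,0.206825,0.0403182
51.000,0.205669,0.0396735
51.500,0.20453,0.0390452
52.000,0.203409,0.0384328
52.500,0.202304,0.0378357
53.000,0.201216,0.0372535
53.500,0.200143,0.0366855
54.000,0.199087,0.0361314
54.500,0.198045,0.0355906
55.000,0.197018,0.0350627
55.500,0.196006,0.0345474
56.000,0.195008,0.0340441
56.500,0.194024,0.0335526
57.000,0.193054,0.0330723
57.500,0.192097,0.0326031
58.000,0.191153,0.0321445
58.500,0.190221,0.0316962
59.000,0.189302,0.0312579
59.500,0.188395,0.0308292
60.000,0.1875,0.03041
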