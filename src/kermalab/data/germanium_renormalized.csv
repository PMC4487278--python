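energy_keV,mu_rho,mu_tr_rho
5.000,216.694,212.598
5.500,167.523,164.207
6.000,132.446,129.716
6.500,106.517,104.191
7.000,87.0595,85.0608
7.500,72.1545,70.4226
8.000,60.5312,59.0191
8.500,51.2218,49.8542
9.000,43.7603,42.521
9.500,37.7057,36.5802
10.000,32.7382,31.7136
10.500,28.8585,27.956
11.000,25.5886,24.7888
11.102,24.9853,24.2045
11.104,175.525,107.265
11.500,159.498,100.889
12.000,141.987,93.6513
12.500,127.001,87.1979
13.000,114.094,81.417
13.500,102.915,76.2164
14.000,93.1796,71.5196
14.500,84.6602,67.2623
15.000,77.1702,63.3902
15.500,70.7424,58.1096
16.000,65.0293,53.4162
16.500,59.9328,49.2293
17.000,55.3705,45.4814
17.500,51.2731,42.1154
18.000,47.5818,39.0831
18.500,44.2469,36.3435
19.000,41.2255,33.8616
19.500,38.4811,31.6071
20.000,35.9822,29.5543
20.500,33.6597,27.7708
21.000,31.5379,26.1342
21.500,29.5951,24.6291
22.000,27.8127,23.2425
22.500,26.1741,21.9625
23.000,24.665,20.7788
23.500,23.2727,19.6825
24.000,21.9858,18.6652
24.500,20.7945,17.72
25.000,19.6899,16.8403
25.500,18.6641,16.0204
26.000,17.7102,15.2552
26.500,16.8219,14.5402
27.000,15.9935,13.8711
27.500,15.22,13.2442
28.000,14.4969,12.6562
28.500,13.82,12.1041
29.000,13.1857,11.5851
29.500,12.5907,11.0966
30.000,12.0318,10.6364
30.500,11.4838,10.141
31.000,10.9691,9.67619
31.500,10.4851,9.23962
32.000,10.0297,8.82918
32.500,9.60059,8.44292
33.000,9.19603,8.07909
33.500,8.81422,7.73606
34.000,8.45359,7.41237
34.500,8.11267,7.10666
35.000,7.79011,6.8177
35.500,7.4847,6.54435
36.000,7.19528,6.28556
36.500,6.92083,6.04037
37.000,6.66038,5.80789
37.500,6.41304,5.58731
38.000,6.17799,5.37787
38.500,5.95446,5.17887
39.000,5.74175,4.98967
39.500,5.53922,4.80966
40.000,5.34625,4.6383
40.500,5.16252,4.46552
41.000,4.98724,4.30118
41.500,4.81994,4.14478
42.000,4.66016,3.99585
42.500,4.50748,3.85394
43.000,4.36151,3.71864
43.500,4.22188,3.58959
44.000,4.08824,3.46641
44.500,3.96028,3.34879
45.000,3.83768,3.23641
45.500,3.72019,3.12898
46.000,3.60751,3.02624
46.500,3.49942,2.92794
47.000,3.39568,2.83383
47.500,3.29606,2.7437
48.000,3.20037,2.65733
48.500,3.10841,2.57455
49.000,3.02,2.49515
49.500,2.93497,2.41897
50.000,2.85315,2.34586
50.500,2.77552,2.27529
51.000,2.70074,2.20752
51.500,2.62868,2.1424
52.000,2.55921,2.07981
52.500,2.49222,2.01961
53.000,2.42759,1.96171
53.500,2.36523,1.906
54.000,2.30504,1.85236
54.500,2.24691,1.80071
55.000,2.19076,1.75095
55.500,2.1365,1.70301
56.000,2.08406,1.65679
56.500,2.03336,1.61222
57.000,1.98433,1.56923
57.500,1.93689,1.52774
58.000,1.89099,1.48771
58.500,1.84655,1.44905
59.000,1.80353,1.41171
59.500,1.76187,1.37565
60.000,1.7215,1.34079
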