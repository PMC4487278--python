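energy_keV,numerator,denominator
5.0,191.22953,191.6975
5.5,157.87682,158.26635
6.0,132.53793,132.8676
6.5,112.51562,112.79775
7.0,96.688113,96.9325
7.5,83.963837,84.17775
8.0,73.584092,73.77304
8.5,64.848001,65.01582
9.0,57.565789,57.71592
9.5,51.433772,51.568945
10.0,46.223192,46.3456
10.5,41.678264,41.789475
11.0,37.763227,37.86475
11.5,34.367814,34.4609
12.0,31.404947,31.49064
12.5,28.804698,28.883875
13.0,26.510815,26.58422
13.5,24.477299,24.545565
14.0,22.666727,22.7304
14.5,21.047956,21.107505
15.0,19.594918,19.65075
15.5,18.270434,18.32286
16.0,17.073864,17.1232
16.5,15.989743,16.036268
17.0,15.004373,15.048332
17.5,14.106281,14.147893
18.0,13.285564,13.325022
18.5,12.53368,12.571157
19.0,11.843225,11.878876
19.5,11.207747,11.241711
20.0,10.621639,10.65404
20.5,10.089623,10.120604
21.0,9.5962157,9.625875
21.5,9.1377762,9.1662025
22.0,8.7111037,8.738378
22.5,8.3133388,8.339535
23.0,7.9419452,7.967131
23.5,7.5946741,7.6189115
24.0,7.2694622,7.292808
24.5,6.9645014,6.987008
25.0,6.6781593,6.699875
25.5,6.4089577,6.429927
26.0,6.1555678,6.175832
26.5,5.9167738,5.936371
27.0,5.6914804,5.710446
27.5,5.4786907,5.4970575
28.0,5.2775054,5.295304
28.5,5.0871195,5.1043785
29.0,4.9067581,4.923504
29.5,4.7357499,4.7520075
30.0,4.5734574,4.58925
30.5,4.4384383,4.453854
31.0,4.3095382,4.324593
31.5,4.1863517,4.2010605
32.0,4.0685671,4.082944
32.5,3.9558168,3.969875
33.0,3.8478421,3.861594
33.5,3.7443714,3.757829
34.0,3.6451915,3.658366
34.5,3.549982,3.562884
35.0,3.4586114,3.471251
35.5,3.3708272,3.3832139
36.0,3.2864544,3.2985972
36.5,3.2053119,3.2172195
37.0,3.1272366,3.1389172
37.5,3.0520787,3.06354
38.0,2.9796811,2.9909306
38.5,2.9099194,2.9209642
39.0,2.8426584,2.8535052
39.5,2.7777762,2.7884314
40.0,2.7151702,2.72564
40.5,2.672071,2.6824284
41.0,2.6301725,2.6404205
41.5,2.5894227,2.5995641
42.0,2.5497868,2.5598244
42.5,2.5112146,2.521151
43.0,2.4736617,2.4834994
43.5,2.4370988,2.4468402
44.0,2.4014865,2.411134
44.5,2.3667843,2.3763401
45.0,2.3329637,2.34243
45.5,2.2999919,2.3093707
46.0,2.2678399,2.2771334
46.5,2.2364796,2.2456896
47.0,2.2058781,2.2150066
47.5,2.176013,2.1850618
48.0,2.1468579,2.1558288
48.5,2.1183881,2.1272827
49.0,2.090585,2.099405
49.5,2.063417,2.072164
50.0,2.0368744,2.04555
50.5,2.0240591,2.0327209
51.0,2.0114412,2.0200896
51.5,1.9990303,2.0076657
52.0,1.9868097,1.9954324
52.5,1.9747819,1.9833923
53.0,1.9629381,1.9715364
53.5,1.9512789,1.9598655
54.0,1.9397934,1.9483686
54.5,1.9284804,1.9370444
55.0,1.9173377,1.925891
55.5,1.9063571,1.9148998
56.0,1.8955347,1.9040672
56.5,1.8848715,1.8933941
57.0,1.8743568,1.8828696
57.5,1.8639956,1.872499
58.0,1.8537814,1.8622756
58.5,1.8437066,1.8521919
59.0,1.8337748,1.8422514
59.5,1.8239772,1.8324453
60.0,1.8143161,1.822776
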