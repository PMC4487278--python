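energy_keV,numerator,denominator
5.0,191.6975,191.6975
5.5,158.26635,158.26635
6.0,132.8676,132.8676
6.5,112.79775,112.79775
7.0,96.9325,96.9325
7.5,84.17775,84.17775
8.0,73.77304,73.77304
8.5,65.01582,65.01582
9.0,57.71592,57.71592
9.5,51.568945,51.568945
10.0,46.3456,46.3456
10.5,41.789475,41.789475
11.0,37.86475,37.86475
11.5,34.4609,34.4609
12.0,31.49064,31.49064
12.5,28.883875,28.883875
13.0,26.58422,26.58422
13.5,24.545565,24.545565
14.0,22.7304,22.7304
14.5,21.107505,21.107505
15.0,19.65075,19.65075
15.5,18.32286,18.32286
16.0,17.1232,17.1232
16.5,16.036268,16.036268
17.0,15.048332,15.048332
17.5,14.147893,14.147893
18.0,13.325022,13.325022
18.5,12.571157,12.571157
19.0,11.878876,11.878876
19.5,11.241711,11.241711
20.0,10.65404,10.65404
20.5,10.120604,10.120604
21.0,9.625875,9.625875
21.5,9.1662025,9.1662025
22.0,8.738378,8.738378
22.5,8.339535,8.339535
23.0,7.967131,7.967131
23.5,7.6189115,7.6189115
24.0,7.292808,7.292808
24.5,6.987008,6.987008
25.0,6.699875,6.699875
25.5,6.429927,6.429927
26.0,6.175832,6.175832
26.5,5.936371,5.936371
27.0,5.710446,5.710446
27.5,5.4970575,5.4970575
28.0,5.295304,5.295304
28.5,5.1043785,5.1043785
29.0,4.923504,4.923504
29.5,4.7520075,4.7520075
30.0,4.58925,4.58925
30.5,4.453854,4.453854
31.0,4.324593,4.324593
31.5,4.2010605,4.2010605
32.0,4.082944,4.082944
32.5,3.969875,3.969875
33.0,3.861594,3.861594
33.5,3.757829,3.757829
34.0,3.658366,3.658366
34.5,3.562884,3.562884
35.0,3.471251,3.471251
35.5,3.3832139,3.3832139
36.0,3.2985972,3.2985972
36.5,3.2172195,3.2172195
37.0,3.1389172,3.1389172
37.5,3.06354,3.06354
38.0,2.9909306,2.9909306
38.5,2.9209642,2.9209642
39.0,2.8535052,2.8535052
39.5,2.7884314,2.7884314
40.0,2.72564,2.72564
40.5,2.6824284,2.6824284
41.0,2.6404205,2.6404205
41.5,2.5995641,2.5995641
42.0,2.5598244,2.5598244
42.5,2.521151,2.521151
43.0,2.4834994,2.4834994
43.5,2.4468402,2.4468402
44.0,2.411134,2.411134
44.5,2.3763401,2.3763401
45.0,2.34243,2.34243
45.5,2.3093707,2.3093707
46.0,2.2771334,2.2771334
46.5,2.2456896,2.2456896
47.0,2.2150066,2.2150066
47.5,2.1850618,2.1850618
48.0,2.1558288,2.1558288
48.5,2.1272827,2.1272827
49.0,2.099405,2.099405
49.5,2.072164,2.072164
50.0,2.04555,2.04555
50.5,2.0327209,2.0327209
51.0,2.0200896,2.0200896
51.5,2.0076657,2.0076657
52.0,1.9954324,1.9954324
52.5,1.9833923,1.9833923
53.0,1.9715364,1.9715364
53.5,1.9598655,1.9598655
54.0,1.9483686,1.9483686
54.5,1.9370444,1.9370444
55.0,1.925891,1.925891
55.5,1.9148998,1.9148998
56.0,1.9040672,1.9040672
56.5,1.8933941,1.8933941
57.0,1.8828696,1.8828696
57.5,1.872499,1.872499
58.0,1.8622756,1.8622756
58.5,1.8521919,1.8521919
59.0,1.8422514,1.8422514
59.5,1.8324453,1.8324453
60.0,1.822776,1.822776
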