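energy_keV,numerator,denominator
5.0,191.50917,191.6975
5.5,158.10454,158.26635
6.0,132.72644,132.8676
6.5,112.6734,112.79775
7.0,96.821762,96.9325
7.5,84.078217,84.17775
8.0,73.682858,73.77304
8.5,64.933743,65.01582
9.0,57.64075,57.71592
9.5,51.499718,51.568945
10.0,46.281531,46.3456
10.5,41.730033,41.789475
11.0,37.809376,37.86475
11.5,34.409125,34.4609
12.0,31.442068,31.49064
12.5,28.838169,28.883875
13.0,26.541089,26.58422
13.5,24.50476,24.545565
14.0,22.691703,22.7304
14.5,21.070727,21.107505
15.0,19.615724,19.65075
15.5,18.289468,18.32286
16.0,17.091309,17.1232
16.5,16.00576,16.036268
17.0,15.019102,15.048332
17.5,14.119845,14.147893
18.0,13.298073,13.325022
18.5,12.54523,12.571157
19.0,11.853902,11.878876
19.5,11.217627,11.241711
20.0,10.630788,10.65404
20.5,10.098112,10.120604
21.0,9.6040972,9.625875
21.5,9.1450981,9.1662025
22.0,8.7179091,8.738378
22.5,8.3196667,8.339535
23.0,7.9478313,7.967131
23.5,7.6001505,7.6189115
24.0,7.2745583,7.292808
24.5,6.9692441,6.987008
25.0,6.6825731,6.699875
25.5,6.413065,6.429927
26.0,6.1593893,6.175832
26.5,5.9203284,5.936371
27.0,5.6947856,5.710446
27.5,5.4817624,5.4970575
28.0,5.2803584,5.295304
28.5,5.0897676,5.1043785
29.0,4.9092139,4.923504
29.5,4.7380251,4.7520075
30.0,4.5755629,4.58925
30.5,4.4403926,4.453854
31.0,4.3113493,4.324593
31.5,4.188027,4.2010605
32.0,4.0701137,4.082944
32.5,3.9572412,3.969875
33.0,3.8491503,3.861594
33.5,3.7455694,3.757829
34.0,3.6462845,3.658366
34.5,3.5509753,3.562884
35.0,3.4595098,3.471251
35.5,3.3716351,3.3832139
36.0,3.2871761,3.2985972
36.5,3.2059514,3.2172195
37.0,3.1277978,3.1389172
37.5,3.0525651,3.06354
38.0,2.9800962,2.9909306
38.5,2.9102664,2.9209642
39.0,2.8429403,2.8535052
39.5,2.7779959,2.7884314
40.0,2.7153305,2.72564
40.5,2.672175,2.6824284
41.0,2.6302221,2.6404205
41.5,2.5894196,2.5995641
42.0,2.5497325,2.5598244
42.5,2.5111107,2.521151
43.0,2.4735097,2.4834994
43.5,2.4369001,2.4468402
44.0,2.4012425,2.411134
44.5,2.3664963,2.3763401
45.0,2.332633,2.34243
45.5,2.2996196,2.3093707
46.0,2.2674273,2.2771334
46.5,2.2360277,2.2456896
47.0,2.2053881,2.2150066
47.5,2.1754859,2.1850618
48.0,2.1462948,2.1558288
48.5,2.1177899,2.1272827
49.0,2.0899526,2.099405
49.5,2.0627514,2.072164
50.0,2.0361764,2.04555
50.5,2.0233249,2.0327209
51.0,2.0106711,2.0200896
51.5,1.9982248,2.0076657
52.0,1.9859692,1.9954324
52.5,1.9739068,1.9833923
53.0,1.9620288,1.9715364
53.5,1.9503358,1.9598655
54.0,1.9388169,1.9483686
54.5,1.9274708,1.9370444
55.0,1.9162954,1.925891
55.5,1.9052824,1.9148998
56.0,1.894428,1.9040672
56.5,1.8837332,1.8933941
57.0,1.8731871,1.8828696
57.5,1.8627949,1.872499
58.0,1.85255,1.8622756
58.5,1.8424449,1.8521919
59.0,1.832483,1.8422514
59.5,1.8226556,1.8324453
60.0,1.8129651,1.822776
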