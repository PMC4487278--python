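energy_keV,numerator,denominator
5.0,191.5295,191.6975
5.5,158.13715,158.26635
6.0,132.7671,132.8676
6.5,112.7192,112.79775
7.0,96.870815,96.9325
7.5,84.129232,84.17775
8.0,73.734946,73.77304
8.5,64.986149,65.01582
9.0,57.693043,57.71592
9.5,51.551599,51.568945
10.0,46.332791,46.3456
10.5,41.780433,41.789475
11.0,37.858829,37.86475
11.5,34.457579,34.4609
12.0,31.489495,31.49064
12.5,28.884558,28.883875
13.0,26.586443,26.58422
13.5,24.54909,24.545565
14.0,22.735029,22.7304
14.5,21.11307,21.107505
15.0,19.65711,19.65075
15.5,18.329889,18.32286
16.0,17.130796,17.1232
16.5,16.044344,16.036268
17.0,15.056814,15.048332
17.5,14.156716,14.147893
18.0,13.334131,13.325022
18.5,12.580505,12.571157
19.0,11.888422,11.878876
19.5,11.25142,11.241711
20.0,10.66388,10.65404
20.5,10.130559,10.120604
21.0,9.6359208,9.625875
21.5,9.1763186,9.1662025
22.0,8.7485462,8.738378
22.5,8.3497395,8.339535
23.0,7.9773578,7.967131
23.5,7.6291485,7.6189115
24.0,7.3030444,7.292808
24.5,6.9972344,6.987008
25.0,6.7100831,6.699875
25.5,6.4401096,6.429927
26.0,6.1859828,6.175832
26.5,5.9464844,5.936371
27.0,5.7205171,5.710446
27.5,5.5070821,5.4970575
28.0,5.3052784,5.295304
28.5,5.1142995,5.1043785
29.0,4.9333689,4.923504
29.5,4.7618139,4.7520075
30.0,4.5989959,4.58925
30.5,4.4635796,4.453854
31.0,4.3342958,4.324593
31.5,4.2107382,4.2010605
32.0,4.0925946,4.082944
32.5,3.9794965,3.969875
33.0,3.8711848,3.861594
33.5,3.7673875,3.757829
34.0,3.667891,3.658366
34.5,3.5723742,3.562884
35.0,3.4807054,3.471251
35.5,3.3926315,3.3832139
36.0,3.3079772,3.2985972
36.5,3.2265611,3.2172195
37.0,3.1482198,3.1389172
37.5,3.072803,3.06354
38.0,3.0001535,2.9909306
38.5,2.9301466,2.9209642
39.0,2.8626468,2.8535052
39.5,2.7975318,2.7884314
40.0,2.734699,2.72564
40.5,2.6915047,2.6824284
41.0,2.6495131,2.6404205
41.5,2.6086721,2.5995641
42.0,2.5689467,2.5598244
42.5,2.5302867,2.521151
43.0,2.4926477,2.4834994
43.5,2.4560003,2.4468402
44.0,2.4203051,2.411134
44.5,2.3855213,2.3763401
45.0,2.3516208,2.34243
45.5,2.3185704,2.3093707
46.0,2.2863413,2.2771334
46.5,2.2549051,2.2456896
47.0,2.2242291,2.2150066
47.5,2.1942906,2.1850618
48.0,2.1650636,2.1558288
48.5,2.1365229,2.1272827
49.0,2.10865,2.099405
49.5,2.0814134,2.072164
50.0,2.0548033,2.04555
50.5,2.0420382,2.0327209
51.0,2.0294701,2.0200896
51.5,2.017109,2.0076657
52.0,2.0049379,1.9954324
52.5,1.9929594,1.9833923
53.0,1.9811647,1.9715364
53.5,1.9695543,1.9598655
54.0,1.9581175,1.9483686
54.5,1.9468529,1.9370444
55.0,1.9357586,1.925891
55.5,1.924826,1.9148998
56.0,1.9140514,1.9040672
56.5,1.903436,1.8933941
57.0,1.8929686,1.8828696
57.5,1.8826547,1.872499
58.0,1.8724876,1.8622756
58.5,1.8624598,1.8521919
59.0,1.8525747,1.8422514
59.5,1.8428236,1.8324453
60.0,1.8332089,1.822776
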