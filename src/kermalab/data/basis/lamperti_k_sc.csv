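energy_keV,numerator,denominator
5.0,191.55541,191.6975
5.5,158.14588,158.26635
6.0,132.7638,132.8676
6.5,112.70738,112.79775
7.0,96.852898,96.9325
7.5,84.106939,84.17775
8.0,73.709506,73.77304
8.5,64.958527,65.01582
9.0,57.663906,57.71592
9.5,51.521439,51.568945
10.0,46.301979,46.3456
10.5,41.749307,41.789475
11.0,37.827597,37.86475
11.5,34.426397,34.4609
12.0,31.458481,31.49064
12.5,28.853801,28.883875
13.0,26.556009,26.58422
13.5,24.519026,24.545565
14.0,22.705369,22.7304
14.5,21.083839,21.107505
15.0,19.628324,19.65075
15.5,18.301583,18.32286
16.0,17.102974,17.1232
16.5,16.017005,16.036268
17.0,15.029955,15.048332
17.5,14.130332,14.147893
18.0,13.308216,13.325022
18.5,12.555051,12.571157
19.0,11.863419,11.878876
19.5,11.226858,11.241711
20.0,10.639751,10.65404
20.5,10.106828,10.120604
21.0,9.6125796,9.625875
21.5,9.1533587,9.1662025
22.0,8.7259589,8.738378
22.5,8.327516,8.339535
23.0,7.9554894,7.967131
23.5,7.6076263,7.6189115
24.0,7.28186,7.292808
24.5,6.9763793,6.987008
25.0,6.6895491,6.699875
25.5,6.4198885,6.429927
26.0,6.1660667,6.175832
26.5,5.9268656,5.936371
27.0,5.7011882,5.710446
27.5,5.4880357,5.4970575
28.0,5.2865074,5.295304
28.5,5.095797,5.1043785
29.0,4.9151281,4.923504
29.5,4.7438283,4.7520075
30.0,4.5812592,4.58925
30.5,4.4460098,4.453854
31.0,4.31689,4.324593
31.5,4.1934935,4.2010605
32.0,4.0755081,4.082944
32.5,3.9625656,3.969875
33.0,3.8544068,3.861594
33.5,3.7507597,3.757829
34.0,3.6514107,3.658366
34.5,3.556039,3.562884
35.0,3.4645126,3.471251
35.5,3.3765787,3.3832139
36.0,3.292062,3.2985972
36.5,3.2107812,3.2172195
37.0,3.1325728,3.1389172
37.5,3.0572867,3.06354
38.0,2.9847657,2.9909306
38.5,2.9148851,2.9209642
39.0,2.8475094,2.8535052
39.5,2.7825166,2.7884314
40.0,2.7198038,2.72564
40.5,2.6766311,2.6824284
41.0,2.6346612,2.6404205
41.5,2.593842,2.5995641
42.0,2.5541385,2.5598244
42.5,2.5155006,2.521151
43.0,2.4778837,2.4834994
43.5,2.4412584,2.4468402
44.0,2.4055855,2.411134
44.5,2.3708241,2.3763401
45.0,2.3369459,2.34243
45.5,2.3039178,2.3093707
46.0,2.2717111,2.2771334
46.5,2.2402972,2.2456896
47.0,2.2096436,2.2150066
47.5,2.1797276,2.1850618
48.0,2.1505229,2.1558288
48.5,2.1220045,2.1272827
49.0,2.0941539,2.099405
49.5,2.0669397,2.072164
50.0,2.0403518,2.04555
50.5,2.0275147,2.0327209
51.0,2.0148753,2.0200896
51.5,2.0024433,2.0076657
52.0,1.990202,1.9954324
52.5,1.9781537,1.9833923
53.0,1.9662897,1.9715364
53.5,1.9546107,1.9598655
54.0,1.9431056,1.9483686
54.5,1.9317733,1.9370444
55.0,1.9206117,1.925891
55.5,1.9096124,1.9148998
56.0,1.8987716,1.9040672
56.5,1.8880903,1.8933941
57.0,1.8775576,1.8828696
57.5,1.8671788,1.872499
58.0,1.8569472,1.8622756
58.5,1.8468553,1.8521919
59.0,1.8369066,1.8422514
59.5,1.8270923,1.8324453
60.0,1.8174148,1.822776
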