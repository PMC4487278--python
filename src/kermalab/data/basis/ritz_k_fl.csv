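energy_keV,numerator,denominator
5.0,191.31748,191.6975
5.5,157.94627,158.26635
6.0,132.59357,132.8676
6.5,112.5606,112.79775
7.0,96.72483,96.9325
7.5,83.994039,84.17775
8.0,73.609085,73.77304
8.5,64.868727,65.01582
9.0,57.583034,57.71592
9.5,51.448149,51.568945
10.0,46.235185,46.3456
10.5,41.688243,41.789475
11.0,37.771511,37.86475
11.5,34.374664,34.4609
12.0,31.410578,31.49064
12.5,28.809285,28.883875
13.0,26.514505,26.58422
13.5,24.480214,24.545565
14.0,22.668973,22.7304
14.5,21.049619,21.107505
15.0,19.596073,19.65075
15.5,18.271145,18.32286
16.0,17.074186,17.1232
16.5,15.989724,16.036268
17.0,15.004053,15.048332
17.5,14.105698,14.147893
18.0,13.284748,13.325022
18.5,12.532659,12.571157
19.0,11.842023,11.878876
19.5,11.206385,11.241711
20.0,10.620134,10.65404
20.5,10.087991,10.120604
21.0,9.5944714,9.625875
21.5,9.1359319,9.1662025
22.0,8.7091707,8.738378
22.5,8.3113272,8.339535
23.0,7.9398641,7.967131
23.5,7.5925316,7.6189115
24.0,7.2672655,7.292808
24.5,6.9622571,6.987008
25.0,6.6758732,6.699875
25.5,6.4066351,6.429927
26.0,6.1532135,6.175832
26.5,5.9143921,5.936371
27.0,5.6890751,5.710446
27.5,5.4762653,5.4970575
28.0,5.2750631,5.295304
28.5,5.0846632,5.1043785
29.0,4.9042904,4.923504
29.5,4.7332731,4.7520075
30.0,4.5709737,4.58925
30.5,4.4359387,4.453854
31.0,4.3070247,4.324593
31.5,4.183826,4.2010605
32.0,4.0660307,4.082944
32.5,3.9532713,3.969875
33.0,3.8452887,3.861594
33.5,3.7418116,3.757829
34.0,3.6426262,3.658366
34.5,3.5474125,3.562884
35.0,3.4560385,3.471251
35.5,3.3682519,3.3832139
36.0,3.2838775,3.2985972
36.5,3.2027342,3.2172195
37.0,3.1246589,3.1389172
37.5,3.0495016,3.06354
38.0,2.9771053,2.9909306
38.5,2.9073454,2.9209642
39.0,2.8400868,2.8535052
39.5,2.7752075,2.7884314
40.0,2.7126048,2.72564
40.5,2.6694926,2.6824284
41.0,2.6275817,2.6404205
41.5,2.58682,2.5995641
42.0,2.5471727,2.5598244
42.5,2.5085896,2.521151
43.0,2.4710262,2.4834994
43.5,2.4344533,2.4468402
44.0,2.3988314,2.411134
44.5,2.3641199,2.3763401
45.0,2.3302905,2.34243
45.5,2.2973102,2.3093707
46.0,2.2651502,2.2771334
46.5,2.233782,2.2456896
47.0,2.2031731,2.2150066
47.5,2.1733008,2.1850618
48.0,2.144139,2.1558288
48.5,2.1156626,2.1272827
49.0,2.0878532,2.099405
49.5,2.0606792,2.072164
50.0,2.0341309,2.04555
50.5,2.0212921,2.0327209
51.0,2.008651,2.0200896
51.5,1.9962171,2.0076657
52.0,1.9839738,1.9954324
52.5,1.9719234,1.9833923
53.0,1.9600573,1.9715364
53.5,1.9483759,1.9598655
54.0,1.9368685,1.9483686
54.5,1.9255337,1.9370444
55.0,1.9143695,1.925891
55.5,1.9033675,1.9148998
56.0,1.8925239,1.9040672
56.5,1.8818398,1.8933941
57.0,1.8713042,1.8828696
57.5,1.8609224,1.872499
58.0,1.8506877,1.8622756
58.5,1.8405927,1.8521919
59.0,1.8306408,1.8422514
59.5,1.8208232,1.8324453
60.0,1.8111423,1.822776
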