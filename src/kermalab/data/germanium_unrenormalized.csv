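energy_keV,mu_rho,mu_tr_rho
5.000,222.2,218
5.500,171.773,168.372
6.000,135.8,133
6.500,109.209,106.824
7.000,89.2546,87.2055
7.500,73.9695,72.194
8.000,62.05,60.5
8.500,52.5035,51.1017
9.000,44.8522,43.582
9.500,38.6437,37.4902
10.000,33.55,32.5
10.500,29.5717,28.6468
11.000,26.2186,25.3992
11.102,25.6,24.8
11.104,180,110
11.500,163.563,103.46
12.000,145.604,96.0369
12.500,130.234,89.418
13.000,116.998,83.4889
13.500,105.532,78.155
14.000,95.5484,73.3378
14.500,86.8113,68.9714
15.000,79.13,65
15.500,72.5379,59.5844
16.000,66.6788,54.7711
16.500,61.452,50.4773
17.000,56.7732,46.6336
17.500,52.5711,43.1816
18.000,48.7857,40.0719
18.500,45.3656,37.2624
19.000,42.2671,34.7171
19.500,39.4527,32.4052
20.000,36.89,30.3
20.500,34.5083,28.471
21.000,32.3324,26.7925
21.500,30.3401,25.2491
22.000,28.5122,23.8271
22.500,26.8319,22.5144
23.000,25.2844,21.3006
23.500,23.8566,20.1763
24.000,22.5369,19.1331
24.500,21.3153,18.1638
25.000,20.1826,17.2617
25.500,19.1308,16.4209
26.000,18.1526,15.6363
26.500,17.2417,14.903
27.000,16.3922,14.2169
27.500,15.5991,13.5741
28.000,14.8576,12.9712
28.500,14.1636,12.405
29.000,13.5132,11.8728
29.500,12.903,11.3719
30.000,12.33,10.9
30.500,11.7681,10.392
31.000,11.2403,9.9154
31.500,10.744,9.46776
32.000,10.277,9.0469
32.500,9.83703,8.65085
33.000,9.4222,8.27779
33.500,9.03071,7.92607
34.000,8.66094,7.59418
34.500,8.31138,7.28073
35.000,7.98065,6.98445
35.500,7.6675,6.70418
36.000,7.37076,6.43885
36.500,7.08937,6.18746
37.000,6.82233,5.94911
37.500,6.56873,5.72296
38.000,6.32774,5.50823
38.500,6.09856,5.3042
39.000,5.88049,5.11023
39.500,5.67284,4.92568
40.000,5.475,4.75
40.500,5.28662,4.57286
41.000,5.10691,4.40439
41.500,4.93537,4.24405
42.000,4.77156,4.09136
42.500,4.61502,3.94588
43.000,4.46536,3.80718
43.500,4.3222,3.67488
44.000,4.18519,3.54861
44.500,4.05399,3.42804
45.000,3.92831,3.31283
45.500,3.80785,3.20271
46.000,3.69234,3.0974
46.500,3.58152,2.99663
47.000,3.47517,2.90017
47.500,3.37305,2.80778
48.000,3.27495,2.71925
48.500,3.18067,2.6344
49.000,3.09004,2.55302
49.500,3.00287,2.47494
50.000,2.919,2.4
50.500,2.83942,2.32768
51.000,2.76276,2.25821
51.500,2.68888,2.19147
52.000,2.61767,2.12732
52.500,2.549,2.06563
53.000,2.48275,2.00629
53.500,2.41883,1.94918
54.000,2.35712,1.89422
54.500,2.29753,1.84128
55.000,2.23998,1.79029
55.500,2.18437,1.74116
56.000,2.13061,1.69379
56.500,2.07865,1.64812
57.000,2.02839,1.60407
57.500,1.97976,1.56156
58.000,1.93271,1.52053
58.500,1.88717,1.48092
59.000,1.84308,1.44267
59.500,1.80037,1.40571
60.000,1.759,1.37
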