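shark_id,sex,size_class,date_tagged,tl_cm,days_detected,receivers_visited,ri,ri_max,roaming_index,kd50_km2
79,F,A,2009-04-30,113.5,29,4,0.015,0.071,0.222,131.793
61,F,C,2009-05-01,212.5,39,1,0.021,0.907,0.056,
53,F,B,2007-11-23,154.5,40,8,0.021,0.159,0.444,254.55
65,F,B,2007-04-24,152,50,8,0.089,0.089,0.444,222.006
84,F,A,2009-05-03,145,103,10,0.055,0.098,0.556,24.745
29,F,C,2007-11-28,208,116,3,0.062,0.126,0.167,
69,F,C,2008-06-09,188,117,2,0.062,0.975,0.111,
73,F,A,2008-06-10,124,142,7,0.076,0.594,0.389,0.316
80,F,A,2009-04-30,144.5,169,14,0.090,0.411,0.778,1.587
33,F,C,2007-11-27,195,171,12,0.091,0.187,0.667,81.087
25,F,A,2007-04-24,125.5,229,9,0.122,0.250,0.500,20.334
58,F,A,2009-05-05,144.5,237,11,0.126,0.587,0.611,0.124
20,F,C,2007-04-23,220,273,4,0.145,0.344,0.222,0.797
6,F,B,2007-05-04,150.5,278,2,0.148,0.955,0.111,0.003
18,F,C,2007-05-01,212,305,6,0.162,0.645,0.333,2.162
7,F,C,2007-04-27,226,307,3,0.163,0.865,0.167,
55,F,C,2009-05-06,206,325,7,0.173,0.405,0.389,0.536
70,F,A,2008-06-10,117,341,10,0.181,0.553,0.556,0.361
50,F,A,2007-11-23,131.5,350,12,0.186,0.207,0.667,3.331
27,F,A,2008-06-10,99,400,6,0.213,0.932,0.333,0.049
82,F,B,2009-05-04,153,431,13,0.229,0.372,0.722,6.642
14,F,A,2007-05-03,113,471,8,0.251,0.329,0.444,3.319
59,F,C,2009-05-05,193.5,485,4,0.258,0.362,0.222,0.458
47,F,A,2007-11-24,113.5,490,8,0.261,0.480,0.444,1.152
72,F,C,2009-05-01,201,492,4,0.262,0.713,0.222,1.368
49,F,A,2007-11-24,113,534,17,0.284,0.438,0.944,57.819
57,F,C,2009-05-06,232.5,555,5,0.295,0.690,0.278,0.003
46,F,C,2007-11-27,218,573,13,0.305,0.450,0.722,37.559
42,F,C,2007-11-25,213,624,5,0.332,0.530,0.278,0.082
2,F,C,2007-04-26,201,693,5,0.369,0.852,0.278,0.002
86,F,C,2009-05-11,181,705,8,0.375,0.770,0.444,2.738
77,F,A,2009-04-29,108,919,17,0.489,0.869,0.944,2.741
64,F,B,2009-05-08,155.5,972,9,0.517,0.575,0.500,17.714
10,F,A,2007-05-04,133.5,1115,13,0.593,0.673,0.722,1.153
13,F,C,2007-04-24,206,1295,6,0.544,0.544,0.333,1.709
81,F,C,2009-04-30,212.5,1566,9,0.833,0.856,0.500,0.414
44,F,C,2007-11-27,212,1567,3,0.834,0.884,0.167,
8,F,C,2007-04-27,223,1732,2,0.887,0.887,0.111,
67,F,C,2008-06-09,187,1973,10,0.915,0.915,0.556,2.191
41,M,C,2007-11-24,183,7,3,0.004,0.037,0.167,12.173
54,M,C,2007-11-23,186,10,1,0.005,0.006,0.056,
24,M,B,2007-04-24,147,16,4,0.009,0.063,0.222,50.980
9,M,B,2007-04-25,134,21,4,0.011,0.389,0.222,69.579
34,M,C,2007-11-28,178.5,40,4,0.021,0.132,0.222,96.753
75,M,A,2009-04-29,103,45,12,0.024,0.039,0.667,41.066
22,M,A,2007-04-22,119,47,1,0.025,0.065,0.056,
16,M,C,2007-05-04,198.5,54,3,0.029,0.684,0.167,1.011
37,M,B,2007-11-27,158.5,58,6,0.031,0.044,0.333,53.623
30,M,C,2007-11-28,196,69,4,0.037,0.116,0.222,11.778
62,M,B,2009-05-07,137.5,81,3,0.043,0.216,0.167,
87,M,C,2009-05-11,196.5,90,5,0.048,0.201,0.278,4.133
28,M,C,2007-11-28,187,103,5,0.055,0.367,0.278,15.344
17,M,A,2007-05-03,110,127,4,0.068,0.143,0.222,0.471
36,M,C,2007-11-27,193,131,5,0.068,0.068,0.278,34.802
52,M,B,2007-11-22,136,181,13,0.096,0.192,0.722,65.855
3,M,C,2007-05-04,183,192,13,0.102,0.169,0.722,26.677
4,M,C,2007-04-27,196.5,232,8,0.123,0.536,0.444,0.093
23,M,A,2007-04-22,117,233,10,0.124,0.270,0.556,78.348
1,M,C,2007-04-24,193.5,239,11,0.127,0.177,0.611,7.862
51,M,B,2007-11-23,159,249,16,0.132,0.144,0.889,44.398
15,M,A,2007-05-03,108,251,5,0.134,0.374,0.278,3.475
56,M,C,2009-05-05,175,292,13,0.155,0.187,0.722,43.719
68,M,A,2009-05-11,108.5,298,11,0.159,0.937,0.611,30.302
85,M,C,2009-05-11,167,327,15,0.174,0.191,0.833,9.204
11,M,B,2007-05-01,156,391,11,0.208,0.250,0.611,3.905
12,M,B,2007-05-04,133.5,493,13,0.262,0.410,0.722,20.443
83,M,C,2009-05-06,172.5,496,10,0.264,0.428,0.556,5.721
48,M,A,2007-11-24,116,507,9,0.270,0.450,0.500,3.071
74,M,A,2009-04-29,104.5,536,14,0.285,0.479,0.778,0.555
65,M,A,2009-05-11,110.5,558,8,0.297,0.669,0.444,0.590
38,M,C,2007-11-27,183.5,615,5,0.327,0.357,0.278,2.886
71,M,C,2009-05-02,178.5,623,9,0.331,0.341,0.500,6.098
66,M,B,2008-06-10,146,633,8,0.337,0.337,0.444,0.364
78,M,C,2009-04-30,202.5,634,14,0.337,0.553,0.778,16.252
63,M,C,2009-05-02,184.5,761,9,0.405,0.562,0.500,5.173
76,M,A,2009-04-29,110.5,837,11,0.445,0.788,0.611,3.843
60,M,C,2009-05-07,188,1115,8,0.593,0.806,0.444,1.593
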