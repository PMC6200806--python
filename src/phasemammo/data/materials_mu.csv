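energy_keV,breast_50_50,adipose,glandular,fiber_nylon,calcification,mass_tumor
10,4.93227,3.5023,6.16078,5.18374,82.5574,6.50312
11,3.75466,2.68868,4.67271,3.9526,62.2169,4.92941
12,2.93729,2.12395,3.63985,3.09808,48.0987,3.83711
13,2.3523,1.71977,2.90064,2.4865,37.9943,3.05535
14,1.92264,1.42292,2.3577,2.03731,30.5729,2.48117
15,1.6,1.2,1.95,1.7,25,2.05
16,1.35303,1.02936,1.63791,1.4418,20.7341,1.71995
17,1.16078,0.896536,1.39498,1.24081,17.4134,1.46304
18,1.0089,0.791601,1.20306,1.08203,14.79,1.26007
19,0.887321,0.707604,1.04943,0.954926,12.6901,1.0976
20,0.788855,0.639573,0.925008,0.851985,10.9893,0.966016
21,0.708258,0.583888,0.823163,0.767725,9.59719,0.858309
22,0.641654,0.53787,0.739,0.698093,8.44676,0.769302
23,0.586133,0.49951,0.668841,0.640049,7.48776,0.695106
24,0.539483,0.467279,0.609892,0.591278,6.68198,0.632764
25,0.5,0.44,0.56,0.55,6,0.58
26,0.466359,0.416757,0.51749,0.51483,5.41893,0.535044
27,0.437519,0.396831,0.481046,0.484678,4.92077,0.496502
28,0.412652,0.37965,0.449624,0.458681,4.49126,0.463271
29,0.391097,0.364758,0.422387,0.436147,4.11895,0.434466
30,0.372321,0.351786,0.398661,0.416518,3.79464,0.409375
31,0.355891,0.340433,0.377898,0.39934,3.51084,0.387417
32,0.34145,0.330456,0.35965,0.384243,3.2614,0.368119
33,0.328706,0.321652,0.343547,0.37092,3.04129,0.351089
34,0.317418,0.313853,0.329283,0.359119,2.84632,0.336005
35,0.307384,0.30692,0.316603,0.348629,2.67299,0.322595
36,0.298433,0.300736,0.305293,0.339271,2.51839,0.310634
37,0.290424,0.295202,0.295173,0.330898,2.38006,0.299931
38,0.283237,0.290236,0.28609,0.323384,2.2559,0.290325
39,0.276767,0.285766,0.277915,0.31662,2.14416,0.28168
40,0.270928,0.281732,0.270537,0.310516,2.04331,0.273877
41,0.265645,0.278082,0.263861,0.304993,1.95206,0.266817
42,0.260854,0.274772,0.257806,0.299983,1.86929,0.260414
43,0.256497,0.271762,0.252301,0.295429,1.79405,0.254592
44,0.252528,0.26902,0.247286,0.29128,1.72549,0.249288
45,0.248904,0.266515,0.242706,0.287491,1.66289,0.244444
46,0.245588,0.264225,0.238516,0.284024,1.60561,0.240013
47,0.242548,0.262124,0.234675,0.280846,1.55311,0.235951
48,0.239757,0.260196,0.231147,0.277928,1.50489,0.23222
49,0.237188,0.258421,0.227902,0.275242,1.46053,0.228788
50,0.234821,0.256786,0.224911,0.272768,1.41964,0.225625
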