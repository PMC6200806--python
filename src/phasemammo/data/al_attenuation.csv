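energy_keV,mu_per_mm
10,7.07948
11,5.34812
12,4.14005
13,3.27127
14,2.63034
15,2.14705
16,1.77907
17,1.49106
18,1.26236
19,1.0784
20,0.928726
21,0.812086
22,0.714543
23,0.632303
24,0.562449
25,0.502709
26,0.451297
27,0.406797
28,0.368071
29,0.334204
30,0.304447
31,0.281575
32,0.261068
33,0.242618
34,0.225966
35,0.210891
36,0.197205
37,0.184747
38,0.173377
39,0.162975
40,0.153438
41,0.146233
42,0.139528
43,0.133277
44,0.12744
45,0.121982
46,0.11687
47,0.112076
48,0.107573
49,0.103338
50,0.0993502
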