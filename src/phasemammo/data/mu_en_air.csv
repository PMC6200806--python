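energy_keV,mu_en_over_rho_m2_per_kg
10,0.4742
11,0.351955
12,0.268093
13,0.208714
14,0.165531
15,0.1334
16,0.108854
17,0.0899269
18,0.0751065
19,0.0633425
20,0.05389
21,0.0463391
22,0.0401271
23,0.0349709
24,0.0306562
25,0.0270187
26,0.0239311
27,0.0212936
28,0.0190275
29,0.0170698
30,0.01537
31,0.0140135
32,0.0128142
33,0.0117499
34,0.0108019
35,0.00995465
36,0.00919498
37,0.00851177
38,0.00789557
39,0.00733829
40,0.006833
41,0.00645715
42,0.0061103
43,0.0057896
44,0.00549253
45,0.00521688
46,0.00496068
47,0.00472217
48,0.00449979
49,0.00429215
50,0.004098
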