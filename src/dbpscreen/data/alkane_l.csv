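n,L
5,2.162
6,2.668
7,3.173
8,3.677
9,4.182
10,4.686
11,5.191
12,5.696
13,6.200
14,6.705
15,7.210
16,7.714
17,8.219
18,8.724
19,9.229
20,9.733
21,10.238
22,10.743
23,11.247
24,11.752
25,12.257
26,12.762
27,13.266
28,13.771
29,14.276
30,14.780
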