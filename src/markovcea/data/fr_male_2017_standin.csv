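age,qx
0,0.00052015915
1,0.00052225155
2,0.00052455979
3,0.00052710613
4,0.00052991513
5,0.00053301388
6,0.00053643228
7,0.00054020329
8,0.00054436328
9,0.00054895238
10,0.00055401485
11,0.00055959951
12,0.00056576023
13,0.00057255641
14,0.0005800536
15,0.0005883241
16,0.00059744768
17,0.0006075123
18,0.00061861503
19,0.00063086293
20,0.00064437409
21,0.00065927879
22,0.00067572074
23,0.00069385845
24,0.00071386679
25,0.00073593864
26,0.00076028675
27,0.00078714582
28,0.00081677472
29,0.00084945898
30,0.00088551357
31,0.00092528589
32,0.00096915911
33,0.0010175559
34,0.0010709423
35,0.0011298325
36,0.0011947936
37,0.0012664508
38,0.001345494
39,0.0014326836
40,0.0015288585
41,0.0016349436
42,0.0017519589
43,0.0018810291
44,0.0020233943
45,0.0021804217
46,0.0023536186
47,0.002544647
48,0.0027553385
49,0.0029877124
50,0.0032439942
51,0.0035266365
52,0.0038383419
53,0.0041820884
54,0.0045611567
55,0.0049791606
56,0.0054400804
57,0.0059482989
58,0.0065086418
59,0.0071264207
60,0.0078074814
61,0.0085582554
62,0.009385817
63,0.010297945
64,0.01130319
65,0.012410947
66,0.013631535
67,0.014976284
68,0.016457625
69,0.018089191
70,0.019885922
71,0.021864182
72,0.024041879
73,0.026438594
74,0.029075716
75,0.031976586
76,0.035166645
77,0.038673582
78,0.042527493
79,0.046761037
80,0.051409584
81,0.05651136
82,0.06210759
83,0.068242603
84,0.074963934
85,0.082322377
86,0.090371999
87,0.0991701
88,0.10877709
89,0.11925629
90,0.13067359
91,0.14309703
92,0.15659617
93,0.17124126
94,0.18710224
95,0.20424747
96,0.22274214
97,0.24264639
98,0.2640131
99,0.28688531
100,0.31129323
101,0.33725099
102,0.36475297
103,0.39376994
104,0.42424502
105,0.45608971
106,0.48918008
107,0.52335349
108,0.5584062
109,0.59409211
110,1
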