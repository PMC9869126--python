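id,group,location,I_S,volume_mm3,I_BA,I_delta
1,A,AcomA,4.0406732118,94.76,35.23238381,8.719434105
2,A,MCA,5.7488915760,135.14,44.95078594,7.819035261
3,A,MCA,5.0767045455,15.97,36.59767886,7.208944018
4,A,MCA,3.3598160151,55.96,36.55615736,10.88040452
5,A,MCA,5.1861500907,59.64,74.14983001,14.29766372
6,B,PcomA,3.2341095028,56.6,71.90187,22.23235577
7,C,MCA,2.2663847780,23.95,6.023658613,2.657826981
8,A,MCA,1.2706231454,10.53,4.906688249,3.861639281
9,A,MCA,2.1621225201,35.08,5.255146491,2.430549815
10,A,AcomA,4.0713882199,49.49,11.77295756,2.891632270
11,A,AcomA,4.3982797173,99.49,46.12817926,10.48777755
12,A,MCA,5.0645315892,297.79,48.15276168,9.507841117
13,C,MCA,2.4047175667,21.37,4.421742621,1.838778359
14,C,PcomA,2.4430479183,21.05,3.200261034,1.309946076
15,B,MCA,8.9100364174,715.49,37.388,4.196166567
16,B,A1,3.3973365112,36.88,14.82702,4.364306632
17,B,MCA,7.9636119609,948.61,34.48276,4.330039907
18,A,MCA,2.6434923391,43.85,11.72072305,4.433802541
19,A,AcomA,2.8428240509,68.09,21.22183611,7.465054371
20,B,MCA,2.0468671840,48.8,8.115747,3.964960471
21,A,MCA,3.5958280061,68.24,10.20929024,2.839204273
22,C,MCA,3.8987811427,34.17,10.1707995,2.608712602
23,B,R_MCA,5.3452695506,266.31,23.29317,4.357717044
24,C,MCA,6.5481566162,356.89,11.59281271,1.770393317
25,A,MCA,2.7343674676,32.18,6.454987332,2.360687584
26,B,MCA,4.5883528390,84.63,17.37567,3.786908664
27,C,MCA,5.6933842239,210,20.37232153,3.578244630
28,A,MCA,3.2346451759,63.05,33.94194816,10.49325237
29,A,PcomA,3.3163436588,129.35,71.10987073,21.44225028
30,C,AcomA,2.0661456072,4.92,2.721671564,1.317269971
31,C,ICA,16.8198177498,1784.64,27.85632782,1.656161097
32,C,PcomA,3.7390956383,106.54,4.830872032,1.291989427
33,A,PcomA,2.3277777778,4.77,6.397712118,2.748420480
34,B,ICA,9.4167033665,1473.81,158.0838,16.78759859
35,B,AcomA,4.0099857592,96.1055,12.62762,3.149043391
36,B,MCA,4.6488589001,85.24,12.1121,2.605392002
37,B,MCA,3.8770003182,153.22,15.87997,4.095942063
38,C,MCA,2.0897745429,4.62,3.918495144,1.875080332
39,A,MCA,5.7870502316,17.44,23.71897186,4.098628993
40,B,MCA,3.1086777238,132.86,7.073861,2.275520806
41,A,MCA,2.1217420081,132.29,7.471530737,3.521413399
42,B,MCA,2.8222266481,237.23,6.861145,2.431110515
43,C,MCA,2.2780536246,31.69,3.741549139,1.642432425
44,B,MCA,4.5506687826,271.35,20.81763,4.574631125
45,B,ICA,17.6140714753,7410.21,58.09859,3.298419229
46,B,MCA,3.4841815541,131.49,11.26017,3.231797156
47,A,MCA,3.0023348637,199.75,8.743103144,2.912101262
48,B,MCA,5.3065290569,254.12,19.03512,3.587112391
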