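allele,D8S1179,D21S11,D18S51,vWA,D3S1358,FGA,TH01,D5S818,D13S317,D7S820,CSF1PO,D16S539,TPOX,D2S1338,D19S433,Penta D,Penta E,D6S1043,D1S80,D12S391
5,,,,,,,,,,,,,,,,,0.0532,,,
6,,,,,,,0.1035,0.0002,,,,,,,,0.0050,0.0002,,,
7,,,,,,,0.2552,0.0140,0.0012,0.0012,0.0022,,0.0002,,,0.0072,0.0022,,,
8,0.0008,,,,,,0.0598,0.0035,0.2662,0.1455,0.0028,0.0090,0.5327,,,0.0425,0.0060,0.0008,,
9,0.0002,,0.0002,,,,0.5192,0.0680,0.1383,0.0630,0.0532,0.2665,0.1222,,0.0002,0.3132,0.0082,0.0020,,
9.1,,,,,,,,,,0.0028,,,,,,,,,,
9.3,,,,,,,0.0390,,,,,,,,,,,,,
10,0.1032,,0.0018,,,,0.0228,0.1930,0.1475,0.1635,0.2305,0.1190,0.0215,,0.0002,0.1140,0.0422,0.0278,,
10.1,,,,,,,,,,0.0008,,,,,,,,,,
11,0.0725,,0.0018,,,,0.0005,0.3378,0.2415,0.3390,0.2422,0.2588,0.2918,,0.0030,0.1600,0.1348,0.0985,0.0620,
11.1,,,,,,,,,,0.0002,,,,,,,,,,
11.2,,,,,,,,,,,,,,,0.0008,,,,,
11.3,,,,,,,,,,,,0.0002,,,,,,,,
12,0.1258,,0.0292,,0.0012,,,0.2408,0.1595,0.2380,0.3830,0.2148,0.0288,,0.0400,0.1810,0.1068,0.1300,0.0398,
12.2,,,,,,,,,,,,,,,0.0048,,,,,
12.3,,,,,,,,,,,,,,,,,,0.0002,,
13,0.2355,,0.2005,0.0028,0.0010,0.0002,,0.1315,0.0357,0.0415,0.0740,0.1158,0.0018,,0.2872,0.1242,0.0503,0.1362,0.1008,
13.2,,,,,,,,,,,,,,,0.0492,,,,,
14,0.2020,,0.2192,0.2525,0.0442,,,0.0098,0.0095,0.0042,0.0107,0.0145,0.0008,,0.2442,0.0420,0.0830,0.1380,0.0792,
14.2,,,,,,,,,,,,,,,0.1122,,,,,
15,0.1725,,0.1785,0.0330,0.3738,,,0.0015,0.0005,0.0002,0.0012,0.0015,0.0002,,0.0670,0.0090,0.0955,0.0162,0.3025,0.0160
15.2,,,,,,,,,,,,,,,0.1448,,,,,
15.3,,,,,,,,,,,,,,,,,,,0.0008,
16,0.0730,,0.1235,0.1855,0.3315,,,,,,,,,0.0078,0.0122,0.0018,0.0775,0.0025,0.2272,0.0085
16.2,,,,,,,,,,,,,,,0.0290,,,,,
16.3,,,,,,,,,,,,,,,,,,,0.0090,0.0002
16.4,,,,,,,,,,,,,,,,,0.0002,,,
17,0.0115,,0.0703,0.2432,0.1840,0.0005,,,,,,,,0.0648,0.0018,,0.0888,0.0435,0.0855,0.0938
17.2,,,,,,,,,,,,,,,0.0028,,,,,
17.3,,,,,,,,,,,,,,,,,,,0.0552,
18,0.0030,,0.0430,0.1842,0.0562,0.0185,,,,,,,,0.1078,0.0005,,0.0790,0.1778,0.0115,0.2298
18.2,,,,,,,,,,,,,,,,,,0.0002,,0.0002
18.3,,,,,,,,,,,,,,,,,,,0.0230,0.0010
18.4,,,,,,,,,,,,,,,,,0.0008,,,
19,,,0.0402,0.0808,0.0072,0.0472,,,,,,,,0.1590,,,0.0595,0.1582,0.0010,0.2245
19.2,,,,,,,,,,,,,,,,,,,,0.0002
19.3,,,,,,,,,,,,,,,,,,,0.0025,
19.4,,,,,,,,,,,,,,,,,0.0008,,,
20,,,0.0365,0.0175,0.0008,0.0545,,,,,,,,0.1270,,,0.0445,0.0528,,0.1645
20.2,,,,,,0.0005,,,,,,,,,,,,,,
20.3,,,,,,,,,,,,,,,,,,0.0005,,
21,,,0.0280,0.0005,,0.1038,,,,,,,,0.0272,,,0.0305,0.0107,,0.1128
21.2,,,,,,0.0032,,,,,,,,,,,,,,
21.3,,,,,,,,,,,,,,,,,,0.0028,,
22,,,0.0138,,,0.1668,,,,,,,,0.0440,,,0.0215,0.0005,,0.0780
22.2,,,,,,0.0062,,,,,,,,,,,,,,
22.3,,,,,,0.0002,,,,,,,,,,,,0.0005,,
23,,,0.0040,,,0.2175,,,,,,,,0.2195,,,0.0088,0.0002,,0.0440
23.2,,,,,,0.0095,,,,,,,,,,,,,,
24,,,0.0055,,,0.1880,,,,,,,,0.1595,,,0.0048,,,0.0165
24.2,,,,,,0.0052,,,,,,,,,,,,,,
25,,,0.0030,,,0.1108,,,,,,,,0.0630,,,0.0010,,,0.0075
25.2,,,,,,0.0048,,,,,,,,,,,,,,
26,,0.0002,0.0010,,,0.0468,,,,,,,,0.0165,,,,,,0.0022
26.2,,,,,,0.0012,,,,,,,,,,,,,,
27,,0.0028,,,,0.0102,,,,,,,,0.0035,,,,,,0.0002
27.2,,,,,,0.0010,,,,,,,,,,,,,,
28,,0.0430,,,,0.0028,,,,,,,,0.0005,,,,,,
28.2,,0.0095,,,,,,,,,,,,,,,,,,
29,,0.2498,,,,0.0002,,,,,,,,,,,,,,
29.2,,0.0032,,,,,,,,,,,,,,,,,,
29.3,,0.0002,,,,,,,,,,,,,,,,,,
30,,0.2960,,,,0.0002,,,,,,,,,,,,,,
30.2,,0.0150,,,,,,,,,,,,,,,,,,
30.3,,0.0052,,,,,,,,,,,,,,,,,,
31,,0.1008,,,,,,,,,,,,,,,,,,
31.2,,0.0718,,,,,,,,,,,,,,,,,,
32,,0.0298,,,,,,,,,,,,,,,,,,
32.2,,0.1265,,,,,,,,,,,,,,,,,,
33,,0.0045,,,,,,,,,,,,,,,,,,
33.2,,0.0372,,,,,,,,,,,,,,,,,,
34.2,,0.0035,,,,,,,,,,,,,,,,,,
35,,0.0002,,,,,,,,,,,,,,,,,,
35.2,,0.0005,,,,,,,,,,,,,,,,,,
36,,0.0002,,,,,,,,,,,,,,,,,,
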