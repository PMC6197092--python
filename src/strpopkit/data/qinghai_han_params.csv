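parameter,D8S1179,D21S11,D18S51,vWA,D3S1358,FGA,TH01,D5S818,D13S317,D7S820,CSF1PO,D16S539,TPOX,D2S1338,D19S433,Penta D,Penta E,D6S1043,D1S80,D12S391
Ho,0.8480,0.8170,0.8590,0.8105,0.7120,0.8600,0.6495,0.7720,0.8150,0.7710,0.7545,0.7970,0.6130,0.8720,0.8065,0.8010,0.9075,0.8645,0.8215,0.8300
He,0.8368,0.8142,0.8530,0.8008,0.7114,0.8585,0.6489,0.7685,0.8031,0.7748,0.7331,0.7881,0.6148,0.8622,0.8147,0.8113,0.9200,0.8733,0.8239,0.8396
MP,0.0492,0.0583,0.0388,0.0710,0.1354,0.0352,0.1694,0.0899,0.0691,0.0840,0.1195,0.0798,0.2074,0.0346,0.0580,0.0586,0.0125,0.0297,0.0510,0.0449
DP,0.9508,0.9417,0.9612,0.9290,0.8646,0.9648,0.8306,0.9101,0.9309,0.9160,0.8805,0.9202,0.7926,0.9654,0.9420,0.9414,0.9875,0.9703,0.9490,0.9551
PIC,0.8162,0.7916,0.8366,0.7711,0.6608,0.8430,0.6027,0.7330,0.7743,0.7417,0.6896,0.7552,0.5545,0.8472,0.7914,0.7875,0.9144,0.8600,0.8041,0.8202
PE(D),0.5034,0.4703,0.5466,0.4275,0.2944,0.5580,0.2430,0.3760,0.4319,0.3887,0.3241,0.4035,0.2035,0.5649,0.4675,0.4585,0.7205,0.5897,0.4920,0.5136
PE(T),0.6909,0.6310,0.7127,0.6187,0.4471,0.7147,0.3545,0.5481,0.6272,0.5464,0.5175,0.5935,0.3068,0.7387,0.6112,0.6009,0.8108,0.7236,0.6395,0.6559
P,0.0005,0.8790,0.5280,0.6165,0.9257,0.7560,0.5982,0.4008,0.6220,0.7011,0.0409,0.6152,0.9133,0.3834,0.8164,0.6454,0.0079,0.1270,0.0642,0.4797
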