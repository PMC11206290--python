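compound_id,iLOGP,XLOGP3,WLOGP,MLOGP,SILICOS-IT,LogP,milogP,logP,logp_average,logp_sd
1,4.21,5.39,5.35,4.24,4.66,5.73,5.61,5.17,5.05,0.60
2,3.98,5.01,4.96,4.03,4.27,5.34,5.13,4.60,4.67,0.52
3,4.09,5.14,4.72,4.24,4.51,5.48,5.26,4.81,4.91,0.61
4,4.17,5.50,5.11,4.45,4.74,5.87,5.77,5.22,5.10,0.61
5,4.28,5.93,5.50,4.65,4.84,6.26,6.03,5.31,5.35,0.71
6,4.08,5.39,5.35,4.24,4.66,5.73,5.44,5.17,5.01,0.61
7,3.83,5.01,4.96,4.03,4.27,5.34,4.96,4.60,4.63,0.53
8,4.06,5.14,4.72,4.24,4.51,5.48,5.09,4.81,4.76,0.48
9,4.01,5.50,5.11,4.45,4.74,5.87,5.60,5.22,5.06,0.63
10,4.28,5.93,5.50,4.65,4.84,6.26,5.86,5.31,5.33,0.69
11,3.99,5.39,5.35,4.24,4.66,5.73,5.14,5.17,4.96,0.60
12,3.67,5.01,4.96,4.03,4.27,5.34,4.66,4.60,4.57,0.55
13,4.12,5.14,4.72,4.24,4.51,5.48,4.79,4.81,4.73,0.45
14,3.77,5.50,5.11,4.45,4.74,5.87,5.30,5.22,5.00,0.66
15,3.97,5.93,5.50,4.65,4.84,6.26,5.55,5.31,5.25,0.74
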