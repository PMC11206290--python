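y,subset,slope,intercept,r
iLOGP,1-5,0.3877,2.8566,0.9403
XLOGP3,1-15,1.0578,1.7233,0.8426
XLOGP3,1-5,1.1972,1.4122,0.9384
XLOGP3,6-10,1.6538,-0.5565,0.9427
XLOGP3,11-15,1.2383,1.0773,0.9577
WLOGP,1-15,0.8350,2.2304,0.7683
WLOGP,1-5,0.9794,1.8705,0.8868
WLOGP,11-15,0.9985,1.6473,0.8919
MLOGP,1-15,0.6500,2.0664,0.7840
MLOGP,6-10,1.0545,0.5279,0.9101
MLOGP,11-15,0.7511,1.7035,0.8795
SILICOS-IT,1-15,0.6630,2.3034,0.8486
SILICOS-IT,1-5,0.7442,2.1287,0.9374
SILICOS-IT,6-10,1.0799,0.7184,0.9892
SILICOS-IT,11-15,0.7588,1.9588,0.9432
LogP,1-15,1.0697,2.0243,0.8484
LogP,1-5,1.2120,1.7050,0.9460
LogP,6-10,1.6739,-0.2866,0.9500
LogP,11-15,1.2499,1.3788,0.9624
logP,6-10,1.4693,-0.2644,0.9877
logP,11-15,1.0652,1.3086,0.9714
milogP,1-15,0.9755,1.9610,0.6499
milogP,1-5,1.2903,1.2684,0.9813
milogP,6-10,1.7585,-0.9371,0.9725
milogP,11-15,1.3037,0.5431,0.9867
logp_average,1-15,0.7369,2.4017,0.7854
logp_average,1-5,0.8307,2.2530,0.9292
logp_average,6-10,1.3129,0.2343,0.9791
logp_average,11-15,0.9300,1.6601,0.9819
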