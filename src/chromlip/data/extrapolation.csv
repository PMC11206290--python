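compound_id,rm0,b,r,c0
1,3.45,-4.77,0.9932,0.7233
2,3.01,-4.09,0.9961,0.7359
3,3.05,-4.23,0.9916,0.7210
4,3.48,-4.89,0.9953,0.7117
5,3.64,-5.14,0.9980,0.7082
6,3.68,-4.85,0.9951,0.7588
7,3.31,-4.34,0.9938,0.7627
8,3.48,-4.60,0.9941,0.7565
9,3.69,-4.88,0.9962,0.7562
10,3.83,-5.04,0.9962,0.7599
11,3.60,-4.75,0.9927,0.7579
12,3.17,-4.25,0.9935,0.7458
13,3.23,-4.21,0.9907,0.7672
14,3.61,-4.69,0.9952,0.7697
15,3.82,-5.01,0.9942,0.7625
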