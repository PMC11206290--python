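compound_id,logp_tlc
1,4.64
2,4.08
3,4.13
4,4.68
5,4.89
6,4.94
7,4.46
8,4.68
9,4.95
10,5.13
11,4.84
12,4.28
13,4.36
14,4.85
15,5.12
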