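compound_id,series,substituent
1,"3',4'-e",dimethylaminobutyl
2,"3',4'-e",dimethylaminopropyl
3,"3',4'-e",pyrrolidinylethyl
4,"3',4'-e",piperidinylethyl
5,"3',4'-e",methylpiperidinylethyl
6,"6',5'-e",dimethylaminobutyl
7,"6',5'-e",dimethylaminopropyl
8,"6',5'-e",pyrrolidinylethyl
9,"6',5'-e",piperidinylethyl
10,"6',5'-e",methylpiperidinylethyl
11,"8',7'-e",dimethylaminobutyl
12,"8',7'-e",dimethylaminopropyl
13,"8',7'-e",pyrrolidinylethyl
14,"8',7'-e",piperidinylethyl
15,"8',7'-e",methylpiperidinylethyl
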