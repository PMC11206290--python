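name,logp_lit,rm0,b,r,logp_tlc
acetanilide,1.21,0.78,-1.62,0.9923,1.21
benzoic acid,1.87,1.16,-2.47,0.9937,1.70
benzophenone,3.18,2.51,-3.28,0.9971,3.43
anthracene,4.45,3.33,-4.12,0.9982,4.49
"p,p'-DDT",6.38,4.69,-5.64,0.9977,6.24
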