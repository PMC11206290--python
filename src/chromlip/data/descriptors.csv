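compound_id,molar_mass,molar_volume,molar_refractivity,surface_area,tpsa,heavy_atoms,aromatic_heavy_atoms,hba,hbd,rotatable_bonds,bioavailability_score,mr_swissadme_synthetic
1,400.55,322.1,121.077,175.12,57.56,29,20,3,0,5,0.55,127.71
2,386.52,305.6,116.446,168.75,57.56,28,20,3,0,4,0.55,123.08
3,398.54,304.6,119.121,174.11,57.56,29,20,3,0,3,0.55,125.66
4,412.56,322.4,123.722,180.48,57.56,30,20,3,0,3,0.55,130.42
5,426.59,342.3,128.258,186.84,57.56,31,20,3,0,3,0.55,134.98
6,400.55,322.1,121.077,175.12,57.56,29,20,3,0,5,0.55,127.71
7,386.52,305.6,116.446,168.75,57.56,28,20,3,0,4,0.55,123.08
8,398.54,304.6,119.121,174.11,57.56,29,20,3,0,3,0.55,125.66
9,412.56,322.4,123.722,180.48,57.56,30,20,3,0,3,0.55,130.42
10,426.59,342.3,128.258,186.84,57.56,31,20,3,0,3,0.55,134.98
11,400.55,322.1,121.077,175.12,57.56,29,20,3,0,5,0.55,127.71
12,386.52,305.6,116.446,168.75,57.56,28,20,3,0,4,0.55,123.08
13,398.54,304.6,119.121,174.11,57.56,29,20,3,0,3,0.55,125.66
14,412.56,322.4,123.722,180.48,57.56,30,20,3,0,3,0.55,130.42
15,426.59,342.3,128.258,186.84,57.56,31,20,3,0,3,0.55,134.98
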