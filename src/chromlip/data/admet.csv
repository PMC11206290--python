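compound_id,water_solubility,caco2_permeability,intestinal_absorption,skin_permeability,vdss,fraction_unbound,bbb_permeability,cns_permeability,total_clearance,max_tolerated_dose,oral_rat_acute,oral_rat_chronic,t_pyriformis_toxicity,minnow_toxicity
1,-5.871,1.003,92.241,-2.697,0.986,0.259,0.478,-1.464,0.672,0.672,2.277,0.449,0.299,1.983
2,-5.783,1.028,92.931,-2.701,0.864,0.253,0.483,-1.402,0.526,0.647,2.272,0.490,0.300,1.944
3,-4.551,1.145,92.725,-2.733,0.868,0.193,0.424,-1.394,0.824,0.537,2.734,0.827,0.291,-0.279
4,-4.660,1.143,92.337,-2.733,0.923,0.189,0.437,-1.381,0.779,0.550,2.756,0.848,0.291,-0.396
5,-5.820,1.021,92.309,-2.711,1.041,0.255,0.535,-1.422,0.599,0.568,2.363,0.542,0.291,1.736
6,-5.793,1.032,95.220,-2.694,1.178,0.268,0.537,-1.493,0.714,0.293,2.361,0.773,0.327,0.423
7,-5.737,1.057,96.401,-2.700,1.062,0.262,0.484,-1.478,0.584,0.258,2.312,0.807,0.331,0.597
8,-4.517,1.226,94.349,-2.723,1.269,0.206,0.559,-1.318,0.832,0.211,3.157,1.074,0.300,-0.872
9,-4.652,1.224,93.960,-2.723,1.328,0.200,0.572,-1.304,0.787,0.228,3.184,1.096,0.299,-0.989
10,-5.829,1.049,95.779,-2.712,1.244,0.257,0.536,-1.498,0.657,0.188,2.413,0.606,0.304,0.389
11,-5.373,1.043,95.329,-2.691,1.332,0.267,0.387,-1.475,0.707,0.594,2.513,0.590,0.299,0.542
12,-5.263,1.068,96.510,-2.697,1.200,0.261,0.357,-1.483,0.562,0.557,2.485,0.610,0.300,0.460
13,-3.965,1.211,93.469,-2.744,1.170,0.200,0.425,-1.370,0.826,0.543,2.949,1.020,0.292,-0.848
14,-4.061,1.209,93.080,-2.743,1.222,0.196,0.438,-1.356,0.781,0.557,2.972,1.041,0.291,-0.965
15,-5.329,1.060,95.888,-2.709,1.368,0.262,0.410,-1.503,0.634,0.483,2.588,0.663,0.291,0.252
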