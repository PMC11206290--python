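y,subset,slope,intercept,r
molar_mass,1-15,42.779,256.508,0.8000
molar_mass,1-5,47.859,245.773,0.8807
molar_mass,6-10,68.869,157.161,0.9216
molar_mass,11-15,49.570,232.152,0.8999
molar_volume,1-15,45.782,160.711,0.8444
molar_volume,1-5,52.381,145.180,0.9518
molar_volume,6-10,69.514,69.288,0.9182
molar_volume,11-15,53.970,131.262,0.9674
molar_refractivity,1-15,13.202,75.913,0.8311
molar_refractivity,1-5,14.871,72.263,0.9213
molar_refractivity,6-10,20.942,46.375,0.9434
molar_refractivity,11-15,15.363,68.170,0.9389
surface_area,1-15,19.960,109.882,0.8017
surface_area,1-5,21.667,105.000,0.8831
surface_area,6-10,31.142,65.010,0.9229
surface_area,11-15,22.437,98.843,0.9021
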