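symbol,atomic_number,mass,neutrons,atomic_radius_pm,atomic_volume_cm3,covalent_radius_pm,vdw_radius_pm,dipole_polarizability_au,electron_affinity_ev,electrophilicity_ev,electronegativity_pauling
H,1,1.008,0,25,14.1,31,120,4.5,0.754,4.01,2.20
Li,3,6.94,4,145,13.1,128,182,164.1,0.618,1.90,0.98
B,5,10.81,6,85,4.6,84,192,20.5,0.280,2.29,2.04
C,6,12.011,6,70,5.3,76,170,11.3,1.262,3.92,2.55
N,7,14.007,7,65,17.3,71,155,7.4,-0.07,3.58,3.04
O,8,15.999,8,60,14.0,66,152,5.3,1.461,4.67,3.44
F,9,18.998,10,50,17.1,57,147,3.74,3.401,7.73,3.98
Na,11,22.990,12,180,23.7,166,227,162.7,0.548,1.75,0.93
Mg,12,24.305,12,150,14.0,141,173,71.2,0.0,1.91,1.31
Al,13,26.982,14,125,10.0,121,184,57.8,0.433,1.85,1.61
Si,14,28.085,14,110,12.1,111,210,37.3,1.390,3.37,1.90
P,15,30.974,16,100,17.0,107,180,25.0,0.746,3.24,2.19
S,16,32.06,16,100,15.5,105,180,19.4,2.077,4.67,2.58
Cl,17,35.45,18,100,22.7,102,175,14.6,3.613,7.34,3.16
K,19,39.098,20,220,45.3,203,275,289.7,0.501,1.53,0.82
Ca,20,40.078,20,180,26.2,176,231,160.8,0.025,1.55,1.00
Fe,26,55.845,30,140,7.1,132,205,62.0,0.151,2.09,1.83
Zn,30,65.38,34,135,9.2,122,210,38.7,0.0,2.35,1.65
Ge,32,72.630,40,125,13.6,120,211,40.0,1.233,3.13,2.01
As,33,74.922,42,115,13.1,119,185,30.0,0.804,3.13,2.18
Se,34,78.971,46,115,16.5,120,190,28.9,2.021,4.48,2.55
Br,35,79.904,44,115,23.5,120,185,21.0,3.364,6.83,2.96
Sn,50,118.710,70,145,16.3,139,217,53.0,1.112,2.87,1.96
I,53,126.904,74,140,25.7,139,198,32.9,3.059,6.18,2.66
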