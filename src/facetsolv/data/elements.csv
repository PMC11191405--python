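element,mass,covalent_radius
H,1.008,0.31
He,4.0026,0.28
B,10.81,0.84
C,12.011,0.76
N,14.007,0.71
O,15.999,0.66
F,18.998,0.57
Ne,20.180,0.58
Na,22.990,1.66
Mg,24.305,1.41
Si,28.085,1.11
P,30.974,1.07
S,32.06,1.05
Cl,35.45,1.02
Ar,39.95,1.06
K,39.098,2.03
Ca,40.078,1.76
Br,79.904,1.20
Kr,83.798,1.16
I,126.90,1.39
Xe,131.29,1.40
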