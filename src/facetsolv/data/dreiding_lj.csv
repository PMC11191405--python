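ff_type,r0,d0,donor_hydrogen,acceptor
H_,3.1950,0.0152,0,0
H__HB,3.1950,0.0001,1,0
C_3,3.8983,0.0951,0,0
C_2,3.8983,0.0951,0,0
C_R,3.8983,0.0951,0,0
C_1,3.8983,0.0951,0,0
N_3,3.6621,0.0774,0,1
N_2,3.6621,0.0774,0,1
N_R,3.6621,0.0774,0,1
N_1,3.6621,0.0774,0,1
O_3,3.4046,0.0957,0,1
O_2,3.4046,0.0957,0,1
O_R,3.4046,0.0957,0,1
F_,3.4720,0.0725,0,0
P_3,4.1500,0.3200,0,0
S_3,4.0300,0.3440,0,1
Cl_,3.9503,0.2833,0,0
Br_,4.2700,0.3700,0,0
I_,4.5100,0.5100,0,0
X_,3.0000,0.1000,0,0
Y_,4.0000,0.4000,0,0
D_H,2.0000,0.0100,1,0
A_X,3.0000,0.1000,0,1
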