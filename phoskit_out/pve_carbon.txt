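gas: carbon
model: platt
P_max: 154.79
alpha: 1.11
beta: 4.51048e-10
respiration_offset: 10
se_P_max: 2.112e-06
se_alpha: 2.655e-08

light_umol_m2_s,rate,residual
0,-10,0
20,10.6815,-2.85602e-07
50,36.64,1.91661e-06
200,107.903,-1.10291e-06
500,140.499,-7.68871e-07
1000,144.671,1.58414e-06
2000,144.79,-5.34619e-07
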