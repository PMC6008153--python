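gas: oxygen
model: platt
P_max: 185.748
alpha: 1.332
beta: 0
respiration_offset: 12
se_P_max: 5.977e-07
se_alpha: 1.62e-08

light_umol_m2_s,rate,residual
0,-12,0
20,12.8178,-6.44939e-09
50,43.968,8.9678e-08
200,129.483,4.64227e-07
500,168.599,-1.85591e-06
1000,173.605,7.53711e-07
2000,173.748,6.71597e-07
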