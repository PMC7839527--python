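key,value
growth_form,liana
b1Bl,0.0096
b2Bl,1.85
b1Bs,0.27
b2Bs,2.57
q,1.0
b1Rd,0.25
b2Rd,0.25
b1Ht,0.1
b2Ht,0.87
reproduction_carbon,0.83
root_beta,0.05
SRA,48.0
K_max,0.12
K_exp,2.06
P50,122.9
wood_capacitance,0.0083
leaf_capacitance,0.0019
stoma_psi_b,160.0
stoma_psi_c,3.0
leaf_TLP,205.02
V_m0,35.54
quantum_efficiency,0.057
stomatal_slope,10.48
root_respiration,0.28
dark_respiration,0.028
growth_respiration,0.35
mort2,15.36
mort3,0.051
leaf_turnover,1.85
root_turnover,1.27
SLA,22.06
rho,0.46
h_max,35.0
gs_min,0.01
mort1,1.0
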