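key,value
growth_form,liana
b1Bl,0.0078
b2Bl,1.9
b1Bs,0.28
b2Bs,2.6
q,1.0
b1Rd,1.05
b2Rd,0.325
b1Ht,0.1
b2Ht,0.87
reproduction_carbon,0.83
root_beta,0.05
SRA,48.0
K_max,0.05
K_exp,2.0
P50,150.0
wood_capacitance,0.0074
leaf_capacitance,0.00075
stoma_psi_b,160.0
stoma_psi_c,3.0
leaf_TLP,225.88
V_m0,21.47
quantum_efficiency,0.069
stomatal_slope,9.025
root_respiration,0.28
dark_respiration,0.013
growth_respiration,0.35
mort2,15.36
mort3,0.05
leaf_turnover,1.85
root_turnover,1.27
SLA,20.326
rho,0.55
h_max,35.0
gs_min,0.01
mort1,1.0
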