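key,value
growth_form,tree
b1Bl,0.009
b2Bl,1.85
b1Bs,0.15
b2Bs,2.35
q,1.0
b1Rd,1.11
b2Rd,0.42
b1Ht,0.083
b2Ht,0.87
reproduction_carbon,0.3
root_beta,0.001
SRA,30.0
K_max,0.009
K_exp,2.0
P50,180.0
wood_capacitance,0.002
leaf_capacitance,0.002
stoma_psi_b,200.0
stoma_psi_c,3.0
leaf_TLP,200.0
V_m0,18.0
quantum_efficiency,0.055
stomatal_slope,9.0
root_respiration,0.28
dark_respiration,0.018
growth_respiration,0.33
mort2,20.0
mort3,0.03
leaf_turnover,0.6
root_turnover,0.6
SLA,16.0
rho,0.62
h_max,35.0
gs_min,0.01
mort1,1.0
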