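name,competition,organ,process
b1Bl,light,leaf,allocation
b2Bl,light,leaf,allocation
b1Bs,unclassified,stem,allocation
b2Bs,unclassified,stem,allocation
q,water,root,allocation
b1Rd,water,root,allocation
b2Rd,water,root,allocation
b1Ht,light,stem,allocation
b2Ht,light,stem,allocation
reproduction_carbon,unclassified,seed,allocation
root_beta,water,root,water use
SRA,water,root,water use
K_max,water,stem,water use
K_exp,water,stem,water use
P50,water,stem,water use
wood_capacitance,water,stem,water use
leaf_capacitance,water,leaf,water use
stoma_psi_b,water,leaf,water use
stoma_psi_c,water,leaf,water use
leaf_TLP,water,leaf,water use
V_m0,light,leaf,photosynthesis
quantum_efficiency,light,leaf,photosynthesis
stomatal_slope,light,leaf,photosynthesis
root_respiration,water,root,respiration
dark_respiration,light,leaf,respiration
growth_respiration,unclassified,entire plant,respiration
mort2,unclassified,entire plant,mortality
mort3,unclassified,entire plant,mortality
leaf_turnover,light,leaf,tissue turnover
root_turnover,water,root,tissue turnover
SLA,light,leaf,structural
rho,unclassified,stem,structural
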