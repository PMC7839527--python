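name,family,a,b,negate,units,printed_median,ed2_default,posterior_median,n_obs,n_studies
b1Bl,uniform,0.005,0.15,0,kg_C/cm^b2Bl,0.0078,0.0086,0.0096,462,4
b2Bl,uniform,1.6,2.2,0,-,1.9,2.0,1.85,462,4
b1Bs,uniform,0.15,0.4,0,kg_C/cm^b2Bs,0.28,0.28,0.27,436,2
b2Bs,uniform,2.2,3.0,0,-,2.6,2.69,2.57,436,2
q,uniform,0.5,1.5,0,g_C/g_C,1.0,1.0,,,
b1Rd,uniform,0.1,2.0,1,m/m^b2Rd,1.05,1.11,0.25,32,1
b2Rd,uniform,0.05,0.6,0,-,0.325,0.42,0.25,32,1
b1Ht,uniform,0.05,0.15,0,-,0.1,0.11,,,
b2Ht,normal,0.87,0.087,0,1/cm,0.87,0.87,,,
reproduction_carbon,uniform,0.7,0.95,0,g_C/g_C,0.83,0.9,,,
root_beta,uniform,0.0001,0.1,0,-,0.05,0.001,,,
SRA,uniform,24.0,72.0,0,m2/kg_C,48.0,48.0,,,
K_max,lognormal,-3.0,0.75,0,kg m-1 s-1 m-1,0.05,0.014,0.12,64,13
K_exp,normal,2.0,0.5,0,-,2.0,1.93,2.06,47,10
P50,normal,150.0,50.0,1,m,150.0,206.2,122.9,61,12
wood_capacitance,lognormal,2.0,0.5,0,kg kg-1 m-1,0.0074,0.0017,0.0083,6,1
leaf_capacitance,lognormal,-0.29,0.76,0,kg kg-1 m-1,0.00075,0.0033,0.0019,7,1
stoma_psi_b,normal,160.0,40.0,1,m,160.0,192.86,,,
stoma_psi_c,uniform,1.0,5.0,0,-,3.0,3.0,,,
leaf_TLP,lognormal,5.42,0.53,1,m,225.88,192.86,205.02,7,1
V_m0,weibull,1.35,40.0,0,umol_C m-2 s-1,21.47,18.75,35.54,39,2
quantum_efficiency,gamma,4.46,59.7,0,-,0.069,0.08,0.057,19,4
stomatal_slope,lognormal,2.2,0.38,0,-,9.025,9.0,10.48,14,1
root_respiration,uniform,0.14,0.42,0,umol_C kg-1 s-1,0.28,0.28,,,
dark_respiration,gamma,2.0,132.0,0,-,0.013,0.014,0.028,26,3
growth_respiration,beta,4.06,7.2,0,g_C/g_C,0.35,0.33,,,
mort2,gamma,1.2,0.058,0,1/year,15.36,15.0,,,
mort3,uniform,0.0,0.1,0,1/year,0.05,0.063,0.051,18,1
leaf_turnover,uniform,1.3,2.4,0,1/year,1.85,1.27,,,
root_turnover,weibull,1.6,1.6,0,1/year,1.27,1.27,,,
SLA,weibull,2.1,12.1,0,m2/kg_C,20.326,17.88,22.06,70,11
rho,uniform,0.1,1.0,0,g/cm3,0.55,0.46,0.46,66,12
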