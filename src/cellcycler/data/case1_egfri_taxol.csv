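parameter,value
n_compartments,50
doubling_time_h,24.0
phase_g1,0.2
phase_s,0.3
phase_g2,0.4
phase_m,0.1
initial_diameter_mm,6.8
growing_layer_mm,0.24
horizon_h,504.0
output_step_h,0.5
rtol,1e-08
atol,1e-10
max_step_h,1.0
drug1_name,EGFRi
drug1_pk_model,kpd_decay
drug1_dose_over_v,1.0
drug1_elimination_rate,0.1
drug1_phase,G1
drug1_damage,1.0
drug1_repair,0.1
drug1_apoptosis,0.0
drug2_name,Taxol
drug2_pk_model,kpd_decay
drug2_dose_over_v,1.0
drug2_elimination_rate,0.1
drug2_phase,M
drug2_damage,1.0
drug2_repair,0.1
drug2_apoptosis,1.0
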