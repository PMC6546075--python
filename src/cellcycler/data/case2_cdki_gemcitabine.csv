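parameter,value
n_compartments,50
doubling_time_h,30.0
phase_g1,0.5
phase_s,0.25
phase_g2,0.15
phase_m,0.1
initial_diameter_mm,6.32
growing_layer_mm,0.46
horizon_h,504.0
output_step_h,0.5
rtol,1e-08
atol,1e-10
max_step_h,1.0
drug1_name,LY2835219
drug1_pk_model,kpd_decay
drug1_dose_over_v,1.0
drug1_elimination_rate,0.1
drug1_phase,G1
drug1_damage,0.4
drug1_repair,0.1
drug1_apoptosis,0.0
drug2_name,Gemcitabine
drug2_pk_model,kpd_decay
drug2_dose_over_v,1.0
drug2_elimination_rate,0.1
drug2_phase,S
drug2_damage,10.0
drug2_repair,0.1
drug2_apoptosis,0.8
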