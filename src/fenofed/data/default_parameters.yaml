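tv_kg: 0.0412
k_ma: 0.198
k_el: 0.27
vc_over_f: 12.9
kg_prime: 0.00971
k_out: 0.00972
e_bile: 0.0239
e_food: 0.617
e_vc1: -0.394
e_vc2: -0.461
mtime1: 0.0
mtime2: 6.94
v_stomach_fasted: 0.049
v_stomach_fed: 1.0
v_duodenum: 0.045
omega_kg: 0.317
omega_kel: 0.863
omega_vc: 0.93
pi_kel: 0.449
pi_vc: 0.509
sigma_prop: 0.608
calorie_unit_kcal: 100.0
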