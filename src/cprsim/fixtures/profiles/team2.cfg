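# fast first shock, tight 2.5-minute cycles
t_first_defib_mean = 10
t_first_defib_sd = 3
shock_interval_mean = 144
shock_interval_sd = 15
peri_shock_pause = 10
cc_segment_mean = 60
cc_segment_sd = 8
cc_pause_mean = 8
cc_pause_sd = 3
vent_rate = 0.5
t_iv = 150
t_intubation = 330
t_epi1 = 400
t_epi2 = 560
t_amiodarone = none
t_atropine = none
cc_output = 1.5
shock_energy = 150
seed = 102
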