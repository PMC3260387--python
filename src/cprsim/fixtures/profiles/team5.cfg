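# guideline-close 2.4-minute cycles, brisk drug administration
t_first_defib_mean = 107
t_first_defib_sd = 10
shock_interval_mean = 142
shock_interval_sd = 12
peri_shock_pause = 11
cc_segment_mean = 55
cc_segment_sd = 8
cc_pause_mean = 9
cc_pause_sd = 3
vent_rate = 1.5
t_iv = 160
t_intubation = 300
t_epi1 = 455
t_epi2 = 600
t_amiodarone = 650
t_atropine = none
cc_output = 1.5
shock_energy = 150
seed = 105
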