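# task-dense team: IV, intubation, adrenaline and amiodarone all between
# the first and third shock; many hands-off pauses, early conversion
t_first_defib_mean = 104
t_first_defib_sd = 10
shock_interval_mean = 186
shock_interval_sd = 20
peri_shock_pause = 14
cc_segment_mean = 45
cc_segment_sd = 8
cc_pause_mean = 12
cc_pause_sd = 4
vent_rate = 1.3
t_iv = 180
t_intubation = 240
t_epi1 = 305
t_epi2 = none
t_amiodarone = 330
t_atropine = none
cc_output = 1.4
shock_energy = 150
seed = 103
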