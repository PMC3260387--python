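# methodical team: long shock cycle, few pauses, late drugs
t_first_defib_mean = 181
t_first_defib_sd = 20
shock_interval_mean = 227
shock_interval_sd = 25
peri_shock_pause = 12
cc_segment_mean = 75
cc_segment_sd = 10
cc_pause_mean = 6
cc_pause_sd = 2
vent_rate = 1.1
t_iv = 210
t_intubation = 420
t_epi1 = 536
t_epi2 = 700
t_amiodarone = none
t_atropine = none
cc_output = 1.2
shock_energy = 150
seed = 101
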