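# compression-focused team: long segments, minimal pauses, late drugs
t_first_defib_mean = 100
t_first_defib_sd = 12
shock_interval_mean = 163
shock_interval_sd = 18
peri_shock_pause = 8
cc_segment_mean = 90
cc_segment_sd = 10
cc_pause_mean = 5
cc_pause_sd = 2
vent_rate = 0.3
t_iv = 240
t_intubation = 500
t_epi1 = 610
t_epi2 = 740
t_amiodarone = none
t_atropine = none
cc_output = 1.8
shock_energy = 150
seed = 104
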