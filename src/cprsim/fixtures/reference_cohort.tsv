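team	median_cardiac_output	no_flow_time_fraction	time_to_rosc	time_to_first_epinephrine	time_to_first_defib	n_indicated_defibs	n_non_indicated_defibs	mean_abs_dev_from_target_interval	mean_defib_interval	n_ventilations_pre_intubation	vent_frequency_pre_intubation
1	1.2	0.21	1089	536	181	5	0	107	227	20	1.1
2	1.5	0.24	728	400	7	6	0	26	144	6	0.5
3	1.4	0.44	463	305	104	3	0	68	186	10	1.3
4	1.8	0.13	761	610	100	5	0	43	163	4	0.3
5	1.5	0.30	532	455	107	4	0	24	142	13	1.5
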