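motive_id	very_high_effector	very_high_non_effector	high_effector	high_non_effector	medium_high_effector	medium_high_non_effector	total
das_general	0	0	7	0	13	15	35
calcification	0	0	4	1	1	4	10
lipoprotein_accumulation	0	0	0	0	2	10	12
inflammation	0	0	3	5	1	11	20
oxidative_stress	0	0	0	1	3	3	7
endothelial_dysfunction	0	0	5	2	2	13	22
raa_system	0	0	0	0	1	4	5
hypertrophy	0	0	1	1	0	8	10
myocardial_fibrosis	1	0	3	1	1	4	10
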