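marker_id	lr_present	lr_absent	assessable	concept_ids
rbd_polysomnographic	130.0	0.65	1
olfactory_loss	6.4	0.40	1
constipation	2.5	0.82	1
erectile_dysfunction	3.4	0.87	1
urinary_dysfunction	2.0	0.90	1
orthostatic_hypotension	3.2	0.80	1
daytime_somnolence	2.7	0.86	1
depression	1.6	0.88	1
diabetes_type2	1.5	1.0	1
subthreshold_parkinsonism	9.6	0.55	0
dat_imaging_deficit	40.0	0.66	0
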