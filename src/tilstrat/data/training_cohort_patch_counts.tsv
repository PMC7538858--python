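patient_id	n_patches	outcome	grade	nodal_status
P1	44	good	III	no
P2	811	good	III	no
P3	810	good	III	no
P4	220	good	III	no
P5	834	good	III	NA
P6	226	good	III	no
P7	171	good	II	yes
P8	92	good	III	no
P9	30	good	III	no
P10	387	good	III	no
P11	471	good	III	yes
P12	228	good	III	no
P13	260	good	II	no
P14	30	good	II	NA
P15	243	good	III	yes
P16	218	poor	III	no
P17	84	poor	III	no
P18	129	poor	NA	yes
P19	82	poor	III	no
P20	290	poor	III	no
P21	113	poor	III	no
P22	144	poor	III	yes
P23	256	poor	III	no
P24	235	poor	III	no
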