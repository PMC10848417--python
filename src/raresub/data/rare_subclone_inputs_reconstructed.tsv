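patient_id	gene	mt_alt	mt_total	purity	major_cn	minor_cn
P25	LRP5	11	2240	0.5167	1	1
P25	PEAK1	62	1000	0.5167	1	1
P65	JAK1	87	1000	0.6149	2	1
P11	TGFBRAP1	94	1250	0.7000	2	1
P26	CD14	21	2000	0.7000	1	1
P39	GHSR	9	1300	0.6000	2	1
P39	NPRL3	17	2600	0.6000	2	1
P12	COL4A2	40	1676	0.6500	2	1
P12	SETD1B	78	1676	0.6500	2	1
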