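mirna	fold_change	p_value	direction	sig_label
gga-miR-375	11.345	0	down	**
gga-miR-217	7.1082	0	down	**
gga-miR-458b-5p	6.9287	4.42E-06	down	**
gga-miR-449c-5p	6.6656	3.46E-05	down	**
gga-miR-124a	6.6656	3.46E-05	down	**
gga-miR-216a	6.5919	1.08E-136	down	**
gga-miR-10a	6.4055	0	up	**
gga-miR-34b	5.8478	8.82E-188	down	**
gga-miR-7	5.8327	0	down	**
gga-miR-216b	5.4757	3.08E-188	down	**
gga-miR-34c	5.2853	0	down	**
gga-miR-137	4.5848	0	down	**
gga-miR-1720-3p	4.1869	1.98E-09	down	**
gga-miR-9-3p	4.0218	6.41E-30	down	**
gga-miR-135a	4.0032	1.33E-134	down	**
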