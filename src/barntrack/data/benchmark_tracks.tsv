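cow_id	sequence	correct_exit	gate_diff_s	track_length_s	correct_length_s
1832	easy	1	2.38	26.06	26.06
1662	easy	1	8.12	46.88	46.88
1733	easy	1	6.44	137.44	137.44
328	easy	1	3.88	170.81	170.81
1553	easy	1	4.06	374.94	374.94
631	easy	1	5.19	86.44	86.44
1761	easy	1	42.88	73.94	73.94
1562	easy	1	2.50	227.00	227.00
1852	easy	1	56.12	129.19	129.19
1758	easy	1	2.62	37.50	37.50
1803	easy	1	22.94	27.06	27.06
1833	easy	1	12.38	71.81	71.81
1582	crowded	1	1.62	1240.44	1240.44
1739	crowded	1	25.38	1212.25	1212.25
1390	crowded	1	5.19	360.31	360.31
1549	crowded	1	3.12	248.94	248.94
1767	crowded	1	0.75	173.94	173.94
1612	crowded	1	0.88	32.31	32.31
1776	crowded	1	1.31	139.56	139.56
324	crowded	1	3.12	75.00	75.00
1634	crowded	1	3.06	197.88	197.88
1527	crowded	1	1.25	99.94	99.94
1639	crowded	1	1.44	151.00	151.00
1792	crowded	1	764.75	1193.56	244.50
1541	crowded	0	1914.50	380.12	40.00
1761	crowded	0	60.62	2126.75	452.50
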