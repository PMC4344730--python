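	O_nubilalis	P_xylostella	T_ni	H_armigera	C_fumiferana	B_mori
O_nubilalis	100.00	81.66	85.21	85.89	82.27	82.39
P_xylostella	81.66	100.00	85.89	83.60	84.22	80.60
T_ni	85.21	85.89	100.00	86.60	82.09	83.98
H_armigera	85.89	83.60	86.60	100.00	83.16	82.19
C_fumiferana	82.27	84.22	82.09	83.16	100.00	79.43
B_mori	82.39	80.60	83.98	82.19	79.43	100.00
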