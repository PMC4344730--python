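	O_nubilalis	P_xylostella	T_ni	H_armigera	C_fumiferana	B_mori
O_nubilalis	100.00	79.01	76.77	75.45	83.11	67.77
P_xylostella	79.01	100.00	78.45	75.33	80.09	73.63
T_ni	76.77	78.45	100.00	88.62	78.47	74.02
H_armigera	75.45	75.33	88.62	100.00	77.46	75.90
C_fumiferana	83.11	80.09	78.47	77.46	100.00	63.84
B_mori	67.77	73.63	74.02	75.90	63.84	100.00
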