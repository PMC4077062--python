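allele	location	localization	growth_urea	growth_thiourea	V_percent	V_err	Km_uM	Km_err	Ki_thiourea_uM	Ki_thiourea_err	Ki_acetamide_uM	Ki_acetamide_err	Ki_guanidine_uM	Ki_guanidine_err
wt		M	+++	---	100		26	2	528	42	237	14	>3000
ureAD	n.a.		---	+++	<2
Y106A	TMS3	M	---	+--	14	3	52	12	978	73	434	24	1650	130
Y106F	TMS3	M	+++	---	29	6	43	4	591	55	312	17	1900	175
A110D	TMS3	M	---	++-	<2
A110G	TMS3	M	++-	++-	42	5	92	6	950	84	495	29	>3000
N275I	TMS7	M	---	+++	<2
N275Q	TMS7	M	+++	+--	91	8	33	4	1035	92	352	26	>3000
Y437A	TMS11	M	---	++-	<2
Y437F	TMS11	M	+++	++-	46	7	88	9	1370	107	102	15	>3000
S446L	TMS11	ER	---	+++	<2
S446T	TMS11	M	+++	---	102	12	24	3	562	37	291	29	>3000
W82A	TMS2	M	---	++-	<2
W82F	TMS2	M	+--	---	50	8	23	5	447	24	198	12	>2500
T133A	ICH3/4	M	---	++-	<2
T133S	ICH3/4	M	+++	+--	72	9	48	3	693	38	316	20	>3000
D286A	TMS7	M	---	+++	<2
D286E	TMS7	M	+++	---	102	10	29	5	555	31	289	24	>3000
Y388A	TMS9	M	---	++-	<2
Y388F	TMS9	M	+++	---	100	5	25	4	602	44	226	23	>3000
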