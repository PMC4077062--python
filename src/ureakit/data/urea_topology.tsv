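label	start	end	compartment
N-ter	1	35	extracellular
TMS1	36	58	membrane
TMS1/TMS2	59	69	intracellular
TMS2	70	92	membrane
TMS2/TMS3	93	101	extracellular
TMS3	102	120	membrane
TMS3/ICH3/4	121	124	intracellular
ICH3/4	125	145	intracellular
TMS4	146	170	membrane
TMS4/TMS5	171	178	extracellular
TMS5	179	200	membrane
TMS5/TMS6	201	212	intracellular
TMS6	213	235	membrane
TMS6/TMS7	236	258	extracellular
TMS7	259	290	membrane
TMS7/TMS8	291	302	intracellular
TMS8	303	326	membrane
TMS8/TMS9	327	350	extracellular
TMS9	351	390	membrane
TMS9/TMS10	391	400	intracellular
TMS10	401	424	membrane
TMS10/TMS11	425	432	extracellular
TMS11	433	455	membrane
TMS11/TMS12	456	460	intracellular
TMS12	461	482	membrane
TMS12/TMS13	483	500	extracellular
TMS13	501	525	membrane
TMS13/TMS14	526	572	intracellular
TMS14	573	595	membrane
TMS14/TMS15	596	605	extracellular
TMS15	606	630	membrane
C-ter	631	700	intracellular
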