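# name toy_midsize
# reactions 9
# metabolite A x 4 external
# metabolite G c 4 balanced
# metabolite F c 4 balanced
# metabolite T c 2 balanced
# metabolite Q c 2 balanced
# metabolite P c 3 balanced
# metabolite C c 1 balanced
# metabolite CO2 x 1 external
# metabolite POut x 3 external
# metabolite QOut x 2 external
# fixed v1 10.0
v1	A#abcd	G#abcd	irr	0.0	inf
v2	G#abcd	F#abcd	rev	-inf	inf
v3	F#abcd	T#ba + T#cd	rev	-inf	inf
v4	T#ab	Q#ab	rev	-inf	inf
v5	Q#ab + T#cd	G#cdab	irr	0.0	inf
v6	G#abcd	P#bcd + C#a	irr	0.0	inf
v7	P#abc	POut#abc	irr	0.0	inf
v8	Q#ab	QOut#ab	irr	0.0	inf
v9	C#a	CO2#a	irr	0.0	inf
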