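# name toy_diamond
# reactions 6
# metabolite A x 2 external
# metabolite B c 2 balanced
# metabolite C1 c 2 balanced
# metabolite C2 c 2 balanced
# metabolite D c 2 balanced
# metabolite E x 2 external
# fixed v1 10.0
v1	A#ab	B#ab	irr	0.0	inf
v2	B#ab	C1#ab	irr	0.0	inf
v3	B#ab	C2#ba	irr	0.0	inf
v4	C1#ab	D#ab	irr	0.0	inf
v5	C2#ab	D#ba	irr	0.0	inf
v6	D#ab	E#ab	irr	0.0	inf
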