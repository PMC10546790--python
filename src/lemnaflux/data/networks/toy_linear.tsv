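# name toy_linear
# reactions 3
# metabolite A x 2 external
# metabolite B c 2 balanced
# metabolite C c 2 balanced
# metabolite D x 2 external
# fixed v1 10.0
v1	A#ab	B#ab	irr	0.0	inf
v2	B#ab	C#ab	irr	0.0	inf
v3	C#ab	D#ab	irr	0.0	inf
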