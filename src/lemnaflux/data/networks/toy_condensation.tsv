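# name toy_condensation
# reactions 5
# metabolite A x 2 external
# metabolite B x 2 external
# metabolite C c 2 balanced
# metabolite D c 2 balanced
# metabolite E c 4 balanced
# metabolite F x 4 external
v1	A#ab	C#ab	irr	0.0	inf
v2	B#ab	D#ab	irr	0.0	inf
v3	C#ab + D#cd	E#abcd	irr	0.0	inf
v4	E#abcd	F#abcd	irr	0.0	inf
vx	C#ab	D#ab	rev	-inf	inf
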