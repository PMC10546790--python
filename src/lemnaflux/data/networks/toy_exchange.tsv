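# name toy_exchange
# reactions 5
# metabolite A x 2 external
# metabolite B x 2 external
# metabolite P c 2 balanced
# metabolite Q c 2 balanced
# metabolite POut x 2 external
# metabolite QOut x 2 external
v1	A#ab	P#ab	irr	0.0	inf
v2	B#ab	Q#ab	irr	0.0	inf
vx	P#ab	Q#ab	rev	-inf	inf
v3	P#ab	POut#ab	irr	0.0	inf
v4	Q#ab	QOut#ab	irr	0.0	inf
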