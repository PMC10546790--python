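# name toy_scramble
# reactions 5
# metabolite A x 4 external
# metabolite S c 4 balanced
# metabolite M c 4 balanced
# metabolite Out x 4 external
# ratio v2a v2b 1.0
v1	A#abcd	S#abcd	irr	0.0	inf
v2a	S#abcd	M#abcd	irr	0.0	inf
v2b	S#abcd	M#dcba	irr	0.0	inf
v3	M#abcd	Out#abcd	irr	0.0	inf
v4	A#abcd	M#abcd	irr	0.0	inf
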