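Pdb	Interaction Energy	Total Energy
complex.pdb	-12.50	1.75
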