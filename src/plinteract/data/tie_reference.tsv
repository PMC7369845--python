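ligand	tie
6	-66.500
2	-61.600
5	-56.800
4	-56.200
8	-36.500
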