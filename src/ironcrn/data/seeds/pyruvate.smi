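# Concentrated pyruvic acid seeds (iron-free): pyruvic acid + water
CC(=O)C(=O)O
O
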