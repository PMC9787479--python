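# Glucose-glycine Maillard seeds (iron-free): glycine + open-chain glucose + water
NCC(=O)O
OCC(O)C(O)C(O)C(O)C=O
O
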