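# Glucose degradation seeds (iron-free): open-chain glucose + water
# (hemiacetal ring forms interconvert with the chain in one reaction step)
OCC(O)C(O)C(O)C(O)C=O
O
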