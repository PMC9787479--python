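# chain-growth toy seed: the 30 AMU monomer (formaldehyde)
C=O
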