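# Concentrated pyruvic acid network: the 31-rule CHO core.
include:
  - cho_core.yaml
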