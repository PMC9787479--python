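# Glucose degradation network: the 31-rule CHO core (38 rules with iron).
include:
  - cho_core.yaml
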