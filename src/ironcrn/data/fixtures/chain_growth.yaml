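# Toy chain-growth system: formaldehyde extends an aldehyde by one CH2O unit,
# so reachable masses are exactly the multiples of 30 AMU within the cap and
# the network has a closed-form size of floor(cap/30) species.
rules:
  - name: Chain Extension by Formaldehyde
    smarts: "[CH2:1]=[O:2].[CX3!H0:3]=[O:4]>>[CH1:1](=[O:2])[C:3][OX2:4]"
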