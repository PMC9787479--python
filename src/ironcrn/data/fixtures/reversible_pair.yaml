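# Toy reversible pair: aldose <-> ketose carbonyl migration encoded as two
# mutually inverse rules.  From glyceraldehyde the network closes after two
# species and two events.
rules:
  - name: Triose Aldose to Ketose
    smarts: "[CX3H1:1](=[O:2])[CX4:3][OX2H1:4]>>[C:1]([OX2:2])[C:3]=[O:4]"
  - name: Triose Ketose to Aldose
    smarts: "[OX2H1:1][CX4H2:2][CX3:3]=[O:4]>>[O:1]=[C:2][C:3][OX2:4]"
    inverse_of: Triose Aldose to Ketose
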