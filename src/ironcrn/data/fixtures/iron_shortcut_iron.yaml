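# Iron rules for the iron-shortcut toy: the Fe3+-catalyzed one-step
# isomerization of glyceraldehyde to lactic acid (the catalyst is mapped
# unchanged through the rule, so it appears on both sides of the event).
rules:
  - name: Fe+3 Catalyzed Glyceraldehyde to Lactic Acid
    iron_dependent: true
    smarts: "[CX3H1:1](=[O:2])[CX4:3]([OX2H1:4])[CX4H2:5][OX2H1:6].[Fe+3:7]>>[C:1](=[O:2])([O:6])[C:3]([O:4])[C:5].[Fe+3:7]"
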