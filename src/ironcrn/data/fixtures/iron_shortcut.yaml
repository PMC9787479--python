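# Toy iron-shortcut system: glyceraldehyde reaches lactic acid in three
# iron-free steps (ketose, enediol, then a benzilic-type 1,2-shift), while a
# single Fe3+-catalyzed isomerization reaches it in one.  Lactic acid is
# therefore catalyzed with gen_free=3, gen_iron=1.
rules:
  - name: Triose Aldose to Ketose
    smarts: "[CX3H1:1](=[O:2])[CX4:3][OX2H1:4]>>[C:1]([OX2:2])[C:3]=[O:4]"
  - name: Ketose Enolization
    smarts: "[OX2H1:1][CX4H2:2][CX3:3]=[O:4]>>[O:1][C:2]=[C:3][OX2:4]"
  - name: Enediol 1,2-Shift to Hydroxy Acid
    smarts: "[OX2H1:1][CX4H2:2][CX3:3]([OX2H1:4])=[CX3:5][OX2H1:6]>>[C:2][C:3]([O:4])[C:5](=[O:6])[O:1]"
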