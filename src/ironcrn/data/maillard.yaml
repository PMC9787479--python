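# Glucose-glycine Maillard network: the CHO core plus the named nitrogen
# mechanisms (Strecker degradation of dicarbonyls by the amino acid, amide
# formation).  This nitrogen set is an explicit reconstruction: only the rules
# named in the reference frequency tables are encoded, so Maillard coverage is
# partial by design.
include:
  - cho_core.yaml
rules:
  # Strecker degradation: a 1,2-dicarbonyl transaminates with an alpha-amino
  # acid; the amino acid decarboxylates and is released as the one-carbon-
  # shorter aldehyde, the dicarbonyl retains the nitrogen as an alpha-amino
  # carbonyl.  The four variants differ in which carbonyl carbon accepts the
  # nitrogen and whether the far carbonyl is substituted (C) or an aldehyde
  # (H); for symmetric dicarbonyls the paired variants coincide, which is why
  # they are applied in equal numbers.
  - name: "Strecker Degradation Dicarbonyl, C, H, C, H"
    smarts: "[#6:9][CX3:1](=[O:2])[CX3H1:3]=[O:4].[NX3H2:5][CX4H2:6][CX3:7](=[O:8])[OX2H1:10]>>[#6:9][C:1](=[O:2])[C:3][N:5].[C:6]=[O:4].[O:8]=[C:7]=[O:10]"
  - name: "Strecker Degradation Dicarbonyl, C, H, H, C"
    smarts: "[#6:9][CX3:1](=[O:2])[CX3H1:3]=[O:4].[NX3H2:5][CX4H2:6][CX3:7](=[O:8])[OX2H1:10]>>[#6:9][C:1]([N:5])[C:3]=[O:4].[C:6]=[O:2].[O:8]=[C:7]=[O:10]"
  - name: "Strecker Degradation Dicarbonyl, H, H, C, H"
    smarts: "[CX3H1:1](=[O:2])[CX3H1:3]=[O:4].[NX3H2:5][CX4H2:6][CX3:7](=[O:8])[OX2H1:10]>>[C:1](=[O:2])[C:3][N:5].[C:6]=[O:4].[O:8]=[C:7]=[O:10]"
  - name: "Strecker Degradation Dicarbonyl, H, H, H, C"
    smarts: "[CX3H1:1](=[O:2])[CX3H1:3]=[O:4].[NX3H2:5][CX4H2:6][CX3:7](=[O:8])[OX2H1:10]>>[C:1]([N:5])[C:3]=[O:4].[C:6]=[O:2].[O:8]=[C:7]=[O:10]"
  - name: "Amide Formation Hydrolysis, C"
    smarts: "[CX3:1](=[O:2])[OX2H1:3].[NX3H2:4][CX4:5]>>[C:1](=[O:2])[N:4][C:5].[O:3]"
    provenance: {note: "carboxylic acid + N-alkyl amine -> amide + water"}
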