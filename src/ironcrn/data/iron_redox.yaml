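# Iron-induced reaction rules (the seven iron rules of the shipped libraries).
# Each couples an organic oxidation/reduction to the Fe2+/Fe3+ redox pair so
# that elementary charge is conserved event-by-event: a two-electron organic
# step consumes or releases two protons and flips two iron ions (four for the
# four-electron carbonyl<->methylene pair).  All were curated from aqueous,
# anoxic, 25-120 C / pH 2-12 chemistry; Fenton-type radical chemistry and
# iron-sulfur clusters are deliberately absent.

rules:
  - name: Fe+2 to Fe+3, α Keto Reduction of a Carboxylic Acid
    iron_dependent: true
    smarts: "[CX3:1](=[O:2])[CX3:3](=[O:4])[OX2H1:5].[Fe+2:6].[Fe+2:7].[#1+:8].[#1+:9]>>[C:1]([OX2:2])[C:3](=[O:4])[O:5].[Fe+3:6].[Fe+3:7]"
    provenance: {note: "alpha-keto acid + 2Fe(II) + 2H+ -> alpha-hydroxy acid + 2Fe(III); pyruvate->lactate-type"}
  - name: Fe+2 to Fe+3, Conversion of α Hydroxy Group of an aldehyde to α Keto group, Inverse
    iron_dependent: true
    inverse_of: Fe+3 to Fe+2, Conversion of α Hydroxy Group of an aldehyde to α Keto group
    smarts: "[CX3H1:1](=[O:2])[CX3:3]=[O:4].[Fe+2:5].[Fe+2:6].[#1+:7].[#1+:8]>>[C:1](=[O:2])[C:3][OX2:4].[Fe+3:5].[Fe+3:6]"
  - name: Fe+2 to Fe+3, Conversion of α Keto Group of an Acid to α Hydro group
    iron_dependent: true
    smarts: "[CX3:1](=[O:2])[CX3:3](=[O:4])[OX2H1:5].[Fe+2:6].[Fe+2:7].[Fe+2:8].[Fe+2:9].[#1+:10].[#1+:11].[#1+:12].[#1+:13]>>[C:1][C:3](=[O:4])[O:5].[O:2].[Fe+3:6].[Fe+3:7].[Fe+3:8].[Fe+3:9]"
    provenance: {note: "four-electron reduction of the alpha-keto group to methylene; releases water"}
  - name: Fe+3 to Fe+2, Aldehyde to acid
    iron_dependent: true
    smarts: "[CX3!H0:1]=[O:2].[OX2H2:3].[Fe+3:4].[Fe+3:5]>>[C:1](=[O:2])[O:3].[Fe+2:4].[Fe+2:5].[#1+].[#1+]"
    provenance: {note: "two-electron aldehyde oxidation with reduction of two Fe(III)"}
  - name: Fe+3 to Fe+2, Conversion of α Hydro Group of an Acid to α Keto group
    iron_dependent: true
    inverse_of: Fe+2 to Fe+3, Conversion of α Keto Group of an Acid to α Hydro group
    smarts: "[CX4!H0;!$([CX4][OX2]):1][CX3:3](=[O:4])[OX2H1:5].[OX2H2:2].[Fe+3:6].[Fe+3:7].[Fe+3:8].[Fe+3:9]>>[C:1](=[O:2])[C:3](=[O:4])[O:5].[Fe+2:6].[Fe+2:7].[Fe+2:8].[Fe+2:9].[#1+].[#1+].[#1+].[#1+]"
  - name: Fe+3 to Fe+2, Conversion of α Hydroxy Group of an aldehyde to α Keto group
    iron_dependent: true
    smarts: "[CX3H1:1](=[O:2])[CX4:3][OX2H1:4].[Fe+3:5].[Fe+3:6]>>[C:1](=[O:2])[C:3]=[O:4].[Fe+2:5].[Fe+2:6].[#1+].[#1+]"
    provenance: {note: "aldose -> osone-type alpha-keto aldehyde; glucose -> glucosone"}
  - name: Fe+3, β elimination from a sugar & Conversion to Acid
    iron_dependent: true
    smarts: "[CX3H1:1](=[O:2])[CX4!H0:3][CX4:4][OX2H1:5].[Fe+3:6].[Fe+3:7]>>[O:2]=[C:1]([O:5])[C:3]=[C:4].[Fe+2:6].[Fe+2:7].[#1+].[#1+]"
    provenance: {note: "coupled beta-dehydration and oxidation of the aldehyde to the unsaturated acid"}
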