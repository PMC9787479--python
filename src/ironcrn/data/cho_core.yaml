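# Core CHO rule set shared by the formose, pyruvic-acid and glucose-degradation
# networks: the 31 named iron-free mechanisms of the sugar interconversion /
# degradation literature (aldol chemistry, Cannizzaro disproportionation,
# keto-enol migrations, ring closures and hemiacetal equilibria, benzilic-type
# rearrangements, decarboxylations, hydrations/eliminations).
#
# Encoding conventions:
#   * reactant patterns are atom-mapped SMARTS; hydrogens are recomputed from
#     valence after the rewrite, so H migration is implicit and balanced;
#   * water/H+/OH-/Fe ions are ordinary pattern participants but do not count
#     toward the 2-molecular-reactant limit;
#   * "Inverse" rules are separate entries, not auto-generated reversals;
#   * chain atoms in ring-closure rules are restricted to acyclic sp3 carbons
#     to keep the generated chemistry at the sugar scale.
#
# These encodings are a reconstruction from mechanism names and the two worked
# rule diagrams available; they reproduce the qualitative chemistry, not any
# particular reference network magnitude.

rules:
  - name: Aldol Condensation
    smarts: "[CX3:1](=[O:2])[CX4!H0:3].[CX3:4]=[O:5]>>[C:1](=[O:2])[C:3][C:4][OX2:5]"
    provenance: {note: "enolizable carbonyl adds to an aldehyde or ketone"}
  - name: Retro Aldol
    smarts: "[CX3:1](=[O:2])[CX4:3][CX4:4][OX2H1:5]>>[C:1](=[O:2])[C:3].[C:4]=[O:5]"
    inverse_of: Aldol Condensation
  - name: Knoevenagel H
    smarts: "[CX3!H0:1]=[O:2].[CX3:3]=[O:4]>>[C:1](=[O:2])[C:3][OX2:4]"
    provenance: {note: "active hydrogen on a carbonyl carbon (formoin/benzoin-type coupling); bootstraps 2 HCHO -> glycolaldehyde"}
  - name: Knoevenagel H, Inverse
    smarts: "[CX3!H0:1](=[O:2])[CX4:3][OX2H1:4]>>[C:1]=[O:2].[C:3]=[O:4]"
    inverse_of: Knoevenagel H
  - name: Knoevenagel C
    smarts: "[CX3:1](=[O:2])[CX4!H0:3].[CX3:4]=[O:5]>>[C:1](=[O:2])[C:3]=[C:4].[O:5]"
    provenance: {note: "active hydrogen on an sp3 alpha carbon; condensation releasing water"}
  - name: Knoevenagel C, Inverse
    smarts: "[CX3:1](=[O:2])[CX3:3]=[CX3:4].[OX2H2:5]>>[C:1](=[O:2])[C:3].[C:4]=[O:5]"
    inverse_of: Knoevenagel C
  # The three Cannizzaro entries partition the chemistry: the plain rule is
  # the disproportionation of substituted aldehydes, and formaldehyde takes
  # part only through the two dedicated crossed rules (one per redox role).
  - name: Canizzaro
    smarts: "[CX3H1;$([CX3H1][#6]):1]=[O:2].[CX3H1;$([CX3H1][#6]):3]=[O:4].[OX2H2:5]>>[C:1](=[O:2])[O:5].[C:3][OX2:4]"
    provenance: {note: "disproportionation of substituted aldehydes to acid + alcohol"}
  - name: Canizzaro 2, HCHO (oxidation)
    smarts: "[CH2:1]=[O:2].[CX3H1;$([CX3H1][#6]):3]=[O:4].[OX2H2:5]>>[C:1](=[O:2])[O:5].[C:3][OX2:4]"
    provenance: {note: "crossed Cannizzaro; formaldehyde is oxidized to formic acid"}
  - name: Canizzaro 2, HCHO (reduction)
    smarts: "[CH2:1]=[O:2].[CX3H1;$([CX3H1][#6]):3]=[O:4].[OX2H2:5]>>[C:1][OX2:2].[C:3](=[O:4])[O:5]"
    provenance: {note: "crossed Cannizzaro; formaldehyde is reduced to methanol"}
  - name: Keto-enol migration twice
    smarts: "[CX3:1](=[O:2])[CX4:3][OX2H1:4]>>[C:1]([OX2:2])[C:3]=[O:4]"
    provenance: {note: "carbonyl 1,2-migration via the enediol (aldose <-> ketose); self-inverse pattern"}
  - name: Elimination + enol to keto
    smarts: "[OX2H1:1][CX4:2][CX3:3]=[CX3:4][OX2H1:5]>>[O:1].[C:2]=[C:3][C:4]=[O:5]"
    provenance: {note: "beta-dehydration of an enol; product written as the keto tautomer"}
  - name: Elimination2
    smarts: "[OX2H1:1][CX4:2][CX4!H0:3][CX3:4]=[O:5]>>[O:1].[C:2]=[C:3][C:4]=[O:5]"
    provenance: {note: "beta-dehydration of a beta-hydroxy carbonyl to the enone"}
  - name: Hydration of C=C(O)
    smarts: "[CX3:1]=[CX3:2][OX2H1:3].[OX2H2:4]>>[O:4][C:1][C:2][O:3]"
    provenance: {note: "water across an enol double bond"}
  - name: Hydration of C(=O)C
    smarts: "[CX3H0;!$([CX3][OX2]):1]=[O:2].[OX2H2:3]>>[C:1]([O:2])[O:3]"
    provenance: {note: "ketone hydration to the gem-diol"}
  - name: Michael Addition 0.2,
    smarts: "[CX3:1](=[O:2])[CX4!H0:3].[CX3:4]=[CX3:5][CX3:6]=[O:7]>>[C:1](=[O:2])[C:3][C:4][C:5][C:6]=[O:7]"
    provenance: {note: "1,4-addition of an enolizable carbonyl to an enone"}
  - name: Michael Addition 0.2, Inverse
    smarts: "[CX3:1](=[O:2])[CX4:3][CX4:4][CX4!H0:5][CX3:6]=[O:7]>>[C:1](=[O:2])[C:3].[C:4]=[C:5][C:6]=[O:7]"
    inverse_of: Michael Addition 0.2,
  - name: Ring Closure 5 membered O, O
    smarts: "[OX2H1:1][CX4;!R:2][CX4;!R:3][CX4;!R:4][CX4;!R:5][OX2H1:6]>>[O:1]1[C:2][C:3][C:4][C:5]1.[O:6]"
    provenance: {note: "1,4-diol etherification; releases water"}
  - name: Ring Closure 6 membered O, O
    smarts: "[OX2H1:1][CX4;!R:2][CX4;!R:3][CX4;!R:4][CX4;!R:5][CX4;!R:6][OX2H1:7]>>[O:1]1[C:2][C:3][C:4][C:5][C:6]1.[O:7]"
  - name: Ring Closure 7 membered O, O
    smarts: "[OX2H1:1][CX4;!R:2][CX4;!R:3][CX4;!R:4][CX4;!R:5][CX4;!R:6][CX4;!R:7][OX2H1:8]>>[O:1]1[C:2][C:3][C:4][C:5][C:6][C:7]1.[O:8]"
  - name: Hemiacetal Formation for 5 membered rings
    smarts: "[OX2H1:1][CX4;!R:2][CX4;!R:3][CX4;!R:4][CX3;!R:5]=[O:6]>>[O:1]1[C:2][C:3][C:4][C:5]1[OX2:6]"
    provenance: {note: "intramolecular hemiacetal (furanose-type lactol)"}
  - name: Hemiacetal Formation for 5 membered rings, Inverse
    smarts: "[O;R:1]1[CX4:2][CX4:3][CX4:4][CX4:5]1[OX2H1:6]>>[OX2:1][C:2][C:3][C:4][C:5]=[O:6]"
    inverse_of: Hemiacetal Formation for 5 membered rings
  - name: Hemiacetal Formation for 6 membered rings
    smarts: "[OX2H1:1][CX4;!R:2][CX4;!R:3][CX4;!R:4][CX4;!R:5][CX3;!R:6]=[O:7]>>[O:1]1[C:2][C:3][C:4][C:5][C:6]1[OX2:7]"
  - name: Hemiacetal Formation for 6 membered rings, Inverse
    smarts: "[O;R:1]1[CX4:2][CX4:3][CX4:4][CX4:5][CX4:6]1[OX2H1:7]>>[OX2:1][C:2][C:3][C:4][C:5][C:6]=[O:7]"
    inverse_of: Hemiacetal Formation for 6 membered rings
  - name: Hemiacetal Formation for 7 membered rings
    smarts: "[OX2H1:1][CX4;!R:2][CX4;!R:3][CX4;!R:4][CX4;!R:5][CX4;!R:6][CX3;!R:7]=[O:8]>>[O:1]1[C:2][C:3][C:4][C:5][C:6][C:7]1[OX2:8]"
  - name: Hemiacetal Formation for 7 membered rings, Inverse
    smarts: "[O;R:1]1[CX4:2][CX4:3][CX4:4][CX4:5][CX4:6][CX4:7]1[OX2H1:8]>>[OX2:1][C:2][C:3][C:4][C:5][C:6][C:7]=[O:8]"
    inverse_of: Hemiacetal Formation for 7 membered rings
  - name: Benzilic Acid Rearrangement
    smarts: "[#6:6][CX3:1](=[O:2])[CX3:3](=[O:4])[#6:7].[OX2H2:5]>>[#6:6][C:1]([#6:7])([OX2:2])[C:3](=[O:4])[O:5]"
    provenance: {note: "1,2-diketone + water -> alpha-hydroxy acid with alkyl migration"}
  - name: Benzilic Acid Rearrangement, Inverse
    smarts: "[#6:6][CX4:1]([#6:7])([OX2H1:2])[CX3:3](=[O:4])[OX2H1:5]>>[#6:6][C:1](=[O:2])[C:3](=[O:4])[#6:7].[O:5]"
    inverse_of: Benzilic Acid Rearrangement
  - name: β Decarboxylation
    smarts: "[CX3:1](=[O:2])[CX4:3][CX3:4](=[O:5])[OX2H1:6]>>[C:1](=[O:2])[C:3].[O:5]=[C:4]=[O:6]"
    provenance: {note: "beta-keto acid loses CO2"}
  - name: α-Keto Acid Decarboxylation
    smarts: "[CX3:1](=[O:2])[CX3:3](=[O:4])[OX2H1:5]>>[C:1]=[O:2].[O:4]=[C:3]=[O:5]"
    provenance: {note: "alpha-keto acid -> aldehyde + CO2"}
  - name: α-β Unsaturated Acid Decarboxylation
    smarts: "[CX3:1]=[CX3:2][CX3:3](=[O:4])[OX2H1:5]>>[C:1]=[C:2].[O:4]=[C:3]=[O:5]"
  - name: β-γ Unsaturated Acid Decarboxylation
    smarts: "[CX3:1]=[CX3:2][CX4:3][CX3:4](=[O:5])[OX2H1:6]>>[C:1]=[C:2][C:3].[O:5]=[C:4]=[O:6]"
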