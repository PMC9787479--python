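# Formose reaction network: the CHO core plus plain keto-enol tautomerization
# (32 iron-free rules).  The enolization rule supplies the enol species that
# "Elimination + enol to keto" and "Hydration of C=C(O)" consume.
include:
  - cho_core.yaml
rules:
  - name: Keto-enol migration
    smarts: "[CX3:1](=[O:2])[CX4!H0:3]>>[C:1]([OX2:2])=[C:3]"
    provenance: {note: "keto -> enol tautomerization; tautomers are distinct species"}
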