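# Experiment presets: seed file + rule files + paper-scale defaults.
# The iron-containing variant of each preset adds the ionic seeds
# (Fe2+, Fe3+, H+, OH-) and the iron_redox rule file.
formose:
  seeds: seeds/formose.smi
  rules: [formose.yaml]
  iron_rules: [iron_redox.yaml]
  generations: 5
  mass_cap: 200
pyruvic:
  seeds: seeds/pyruvate.smi
  rules: [pyruvate.yaml]
  iron_rules: [iron_redox.yaml]
  generations: 5
  mass_cap: 200
glucose_degradation:
  seeds: seeds/glucose.smi
  rules: [glucose.yaml]
  iron_rules: [iron_redox.yaml]
  generations: 4
  mass_cap: 200
maillard:
  seeds: seeds/maillard.smi
  rules: [maillard.yaml]
  iron_rules: [iron_redox.yaml]
  generations: 3
  mass_cap: 200
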