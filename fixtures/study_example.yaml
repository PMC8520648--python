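# Minimal example study configuration (see `ordbench study --help`).
seed: 11
out_dir: study_out
type1_B: 200
type1_methods: [MWU, OLR]
subgroup_tags: [prevention]
battery:
  bootstrap_B: 300
scenarios:
  - name: stroke3_benefit
    n_datasets: 6
    tags_cycle:
      - {prevention: primary}
      - {prevention: secondary}
    sim:
      scale: stroke3
      n_per_arm: 400
      treatment_logOR: -0.3
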