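# desk-scale synthetic run: 50 regions, 60 subjects, reduced resampling
outdir: results/toy
simulate: true
sim:
  n_regions: 50
  n_modules: 5
  n_subjects: 60
  n_template_subjects: 20
n_boot: 300
n_perm: 300
seed: 11
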