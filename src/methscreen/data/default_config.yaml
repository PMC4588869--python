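# Bundled synthetic scenario: 24-sample array screen with one fully
# planted promoter ROI, gene sets, and a 175-subject validation cohort.
outdir: methscreen_out
seed: 0
simulate:
  n_regions: 600
  n_true_dmrs: 12
  cluster_dmrs: true
  windows_per_roi: 20
  seed: 0
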