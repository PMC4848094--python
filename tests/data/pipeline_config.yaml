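# Small end-to-end fixture: 250 genes, shallow libraries, one planted
# short-ORF gene group with an extra TE decrease beyond the length trend.
seed: 7
outdir: out
simulate:
  n_genes: 250
  library_depth: 20000
  nb_dispersion: 0.01
  contamination_frac: 0.2
  group_defs:
    - name: short_set
      quantile_range: [0.0, 0.2]
      size: 40
      extra_shift_log2: -0.3
count:
  start_off: 12
  stop_off: 18
  excl_codons: 30
te:
  min_pooled: 128
lengthprofile:
  bin_size: 50
groups:
  alternative: less
  length_correct: true
  min_size: 21
trace:
  smooth_window: 40
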