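# Demo configuration: the full pipeline on a small synthetic cohort.
# Study-scale settings (349/437 features, 101 subsets, 30x50 CV with 500
# trees) are the package defaults; this file scales the expensive stages
# down so the end-to-end run finishes in well under a minute.
seed: 20170109
design:
  n_subjects: 16
  n_outliers: 3
layers:
  metabolite:
    n_features: 40
  protein:
    n_features: 40
robustness:
  n_random: 20
classification:
  n_outer: 5
  n_inner: 8
  n_trees: 50
  panel_size: 10
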