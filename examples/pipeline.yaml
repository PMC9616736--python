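# End-to-end demo: simulate a small brain sample, run QC + doublet
# removal, fuse over-split clusters, test differential expression
# between hydration conditions, classify calcium traces, and profile
# astrocyte-synapse distances.
seed: 3
stages: [simulate, qc, fuse, de, calcium, vicinity]
simulate:
  n_cells: 200
  n_genes: 2000
  doublet_rate: 0.04
  n_qc_violators: 5
  de:
    - [gene0400, 2.0]
    - [gene0401, -2.0]
de:
  min_nonzero_cells: 60
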