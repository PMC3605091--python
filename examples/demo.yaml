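# Demo pipeline config: fully synthetic end-to-end run at study scale.
mode: synthetic
seed: 42
temperature: 298.15
n_snapshots: 2000
n_clusters: 10
k: 10
n_late_snapshots: 3
contexts: [direct, full, path1, path2]
share_threshold: 0.8
contact_cutoff: 4.5
gap_samples: 5
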