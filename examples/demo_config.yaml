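# Demo pipeline configuration: synthetic cohort of 6 x 2,000 records.
simulation:
  n_per_stratum: 2000
  seed: 1
  weight_cv: 0.5
top_k: 20
min_support: 0.0
edge_threshold: 0.0
graph_format: graphml
strata: ["male:poor", "female:poor", "all:poor", "all:normal", "all:good"]
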