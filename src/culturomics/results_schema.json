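{
  "sections": {
    "config": "object",
    "samples": "object",
    "partition": "object",
    "cultivability": "object",
    "rare_biosphere": "object",
    "phylo": "object_or_null",
    "ordination": "object",
    "richness_tests": "object",
    "percentile_correlation": "object"
  },
  "required_keys": [
    "cultivability.cultivable_fraction",
    "cultivability.medium_gain",
    "partition.rumen_all",
    "partition.plates_all",
    "partition.shared",
    "rare_biosphere.n_otus",
    "ordination.pcoa",
    "ordination.permanova",
    "percentile_correlation.cells"
  ]
}
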