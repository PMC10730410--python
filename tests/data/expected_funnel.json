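{
  "significant_eqtls": 86,
  "in_accessibility": 78,
  "in_regulatory": 71,
  "post_qc": 71,
  "index_eqtls": 71,
  "replicated_loci": 3,
  "selected_genes": 1
}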