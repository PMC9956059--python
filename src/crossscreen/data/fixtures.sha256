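a995a8a3f8990d398f1601890eb5c54c7591f3e7623985a0f6e413ad046771ac  candidate_snps.tsv
e5ec1d2dbc4f55e2196d8085e7833779ba7295d70668ed2482d779a5562db188  sequencing_stats.tsv
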