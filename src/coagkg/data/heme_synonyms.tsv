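# names curated to the single canonical entity a(CHEBI:heme)
heme
hemin
hematin
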