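# manually curated literature-screening statuses for gap candidates
symbol	literature_status
F10	screened_negative
F11	screened_negative
SERPINC1	screened_negative
F13A1	screened_negative
TFPI	screened_negative
FCER1G	screened_positive_external_celltype
PIK3CA	screened_positive_external_celltype
MYH9	screened_positive_external_celltype
SRC	screened_positive_external_celltype
MAPK1	screened_positive_external_celltype
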