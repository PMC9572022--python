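source	interaction	target	source_class	target_class
F3	binding	F7	protein	protein
F7	activation	F10	protein	protein
TFPI	inhibition	F3	protein	protein
TFPI	inhibition	F10	protein	protein
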