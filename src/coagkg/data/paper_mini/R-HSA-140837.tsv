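source	interaction	target	source_class	target_class
KLKB1	activation	F12	protein	protein
KNG1	binding	KLKB1	protein	protein
F12	activation	F11	protein	protein
F11	activation	F9	protein	protein
F9	activation	F10	protein	protein
F8	binding	F9	protein	protein
VWF	binding	F8	protein	protein
PROC	inhibition	F8	protein	protein
PROS1	binding	PROC	protein	protein
SERPINC1	inhibition	F9	protein	protein
SERPING1	inhibition	F12	protein	protein
A2M	inhibition	KLKB1	protein	protein
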