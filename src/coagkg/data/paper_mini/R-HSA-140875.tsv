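source	interaction	target	source_class	target_class
F10	activation	F2	protein	protein
F5	binding	F10	protein	protein
F2	activation	F5	protein	protein
F2	activation	F8	protein	protein
F2	conversion	FGA	protein	protein
FGB	binding	FGA	protein	protein
FGG	binding	FGA	protein	protein
FGA	conversion	fibrin	protein	metabolite
F2	activation	F13A1	protein	protein
F13A1	activation	fibrin	protein	metabolite
PROC	inhibition	F5	protein	protein
PROC	inhibition	F8	protein	protein
SERPINC1	inhibition	F2	protein	protein
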