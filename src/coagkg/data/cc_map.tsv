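go_id	compartment
GO:0005576	extracellular
GO:0005615	extracellular
GO:0031012	extracellular
GO:0016020	membrane
GO:0005886	membrane
GO:0009897	membrane
GO:0009986	membrane
GO:0005622	intracellular
GO:0005737	intracellular
GO:0005829	intracellular
GO:0005634	intracellular
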