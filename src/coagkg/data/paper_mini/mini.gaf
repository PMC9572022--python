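!gaf-version: 2.2
! synthetic GO CC annotations for the paper-mini fixture proteins
HGNC	KLKB1	KLKB1	located_in	GO:0005615	PMID:90000000	IDA		C	KLKB1		protein	taxon:9606	20220101	synthetic
HGNC	F12	F12	located_in	GO:0005615	PMID:90000000	IDA		C	F12		protein	taxon:9606	20220101	synthetic
HGNC	F11	F11	located_in	GO:0005615	PMID:90000000	IDA		C	F11		protein	taxon:9606	20220101	synthetic
HGNC	F10	F10	located_in	GO:0005615	PMID:90000000	IDA		C	F10		protein	taxon:9606	20220101	synthetic
HGNC	F9	F9	located_in	GO:0005615	PMID:90000000	IDA		C	F9		protein	taxon:9606	20220101	synthetic
HGNC	F8	F8	located_in	GO:0005615	PMID:90000000	IDA		C	F8		protein	taxon:9606	20220101	synthetic
HGNC	F7	F7	located_in	GO:0005615	PMID:90000000	IDA		C	F7		protein	taxon:9606	20220101	synthetic
HGNC	F5	F5	located_in	GO:0005615	PMID:90000000	IDA		C	F5		protein	taxon:9606	20220101	synthetic
HGNC	F2	F2	located_in	GO:0005615	PMID:90000000	IDA		C	F2		protein	taxon:9606	20220101	synthetic
HGNC	FGA	FGA	located_in	GO:0005615	PMID:90000000	IDA		C	FGA		protein	taxon:9606	20220101	synthetic
HGNC	FGB	FGB	located_in	GO:0005615	PMID:90000000	IDA		C	FGB		protein	taxon:9606	20220101	synthetic
HGNC	FGG	FGG	located_in	GO:0005615	PMID:90000000	IDA		C	FGG		protein	taxon:9606	20220101	synthetic
HGNC	F13A1	F13A1	located_in	GO:0005615	PMID:90000000	IDA		C	F13A1		protein	taxon:9606	20220101	synthetic
HGNC	VWF	VWF	located_in	GO:0005615	PMID:90000000	IDA		C	VWF		protein	taxon:9606	20220101	synthetic
HGNC	PROC	PROC	located_in	GO:0005615	PMID:90000000	IDA		C	PROC		protein	taxon:9606	20220101	synthetic
HGNC	PROS1	PROS1	located_in	GO:0005615	PMID:90000000	IDA		C	PROS1		protein	taxon:9606	20220101	synthetic
HGNC	KNG1	KNG1	located_in	GO:0005615	PMID:90000000	IDA		C	KNG1		protein	taxon:9606	20220101	synthetic
HGNC	SERPINC1	SERPINC1	located_in	GO:0005615	PMID:90000000	IDA		C	SERPINC1		protein	taxon:9606	20220101	synthetic
HGNC	SERPING1	SERPING1	located_in	GO:0005615	PMID:90000000	IDA		C	SERPING1		protein	taxon:9606	20220101	synthetic
HGNC	A2M	A2M	located_in	GO:0005615	PMID:90000000	IDA		C	A2M		protein	taxon:9606	20220101	synthetic
HGNC	TFPI	TFPI	located_in	GO:0005615	PMID:90000000	IDA		C	TFPI		protein	taxon:9606	20220101	synthetic
HGNC	MMP9	MMP9	located_in	GO:0005615	PMID:90000000	IDA		C	MMP9		protein	taxon:9606	20220101	synthetic
HGNC	F3	F3	located_in	GO:0005886	PMID:90000000	IDA		C	F3		protein	taxon:9606	20220101	synthetic
HGNC	GP6	GP6	located_in	GO:0005886	PMID:90000000	IDA		C	GP6		protein	taxon:9606	20220101	synthetic
HGNC	ITGA2B	ITGA2B	located_in	GO:0005886	PMID:90000000	IDA		C	ITGA2B		protein	taxon:9606	20220101	synthetic
HGNC	ITGB3	ITGB3	located_in	GO:0005886	PMID:90000000	IDA		C	ITGB3		protein	taxon:9606	20220101	synthetic
HGNC	TLR4	TLR4	located_in	GO:0005886	PMID:90000000	IDA		C	TLR4		protein	taxon:9606	20220101	synthetic
HGNC	CLEC1B	CLEC1B	located_in	GO:0005886	PMID:90000000	IDA		C	CLEC1B		protein	taxon:9606	20220101	synthetic
HGNC	SYK	SYK	located_in	GO:0005829	PMID:90000000	IDA		C	SYK		protein	taxon:9606	20220101	synthetic
HGNC	PLCG2	PLCG2	located_in	GO:0005829	PMID:90000000	IDA		C	PLCG2		protein	taxon:9606	20220101	synthetic
HGNC	AKT1	AKT1	located_in	GO:0005829	PMID:90000000	IDA		C	AKT1		protein	taxon:9606	20220101	synthetic
HGNC	NOS3	NOS3	located_in	GO:0005829	PMID:90000000	IDA		C	NOS3		protein	taxon:9606	20220101	synthetic
HGNC	PRKCA	PRKCA	located_in	GO:0005829	PMID:90000000	IDA		C	PRKCA		protein	taxon:9606	20220101	synthetic
HGNC	SYK	SYK	enables	GO:0004715	PMID:90000000	IDA		F	SYK		protein	taxon:9606	20220101	synthetic
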