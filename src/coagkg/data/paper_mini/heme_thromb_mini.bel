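# Synthetic hand-encoded mini corpus of reported heme effects on the blood
# coagulation system and platelet activation.  Citations are synthetic
# PMID-like placeholders; statements paraphrase published findings for use
# as an offline test fixture.
SET DOCUMENT Name = "heme-thromb-mini"
SET DOCUMENT Version = "1.0"
DEFINE NAMESPACE HGNC AS "HGNC gene symbols"
DEFINE NAMESPACE CHEBI AS "ChEBI names"
DEFINE NAMESPACE GO AS "GO process names"
DEFINE NAMESPACE MESH AS "MeSH terms"
DEFINE NAMESPACE TEXT AS "free-text entities"

UNSET ALL
SET Citation = "90000001"
SET Evidence = "plasma kallikrein is activated in the presence of heme"
SET Setting = "in vitro"
SET Dose = "up to 24 nmol"
a(CHEBI:heme) => act(p(HGNC:KLKB1))

UNSET ALL
SET Citation = "90000001"
SET Evidence = "heme-triggered autoactivation of FXII has been suggested"
SET Setting = "in vitro"
a(CHEBI:heme) -> act(p(HGNC:F12))

UNSET ALL
SET Citation = "90000002"
SET Evidence = "high-affinity heme binding to FVIII abolishes clotting; KD reading attributed to FVIII"
SET Setting = "in vitro"
SET KD = "1.9 nM"
complex(a(CHEBI:heme), p(HGNC:F8)) =| act(p(HGNC:F8))

UNSET ALL
SET Citation = "90000003"
SET Evidence = "high-affinity heme binding to FVIIIa; alternate KD reading attributed to FVIIIa"
SET Setting = "in vitro"
SET KD = "12.7 nM"
complex(a(CHEBI:heme), p(HGNC:F8)) =| act(p(HGNC:F8))

UNSET ALL
SET Citation = "90000002"
SET Evidence = "heme binding to FVIII abolishes its interaction with FIX"
SET Setting = "in vitro"
a(CHEBI:heme) -| complex(p(HGNC:F8), p(HGNC:F9))

UNSET ALL
SET Citation = "90000004"
SET Evidence = "persistent FVIII-VWF complex formation and platelet binding in the presence of heme"
SET Setting = "in vitro"
a(CHEBI:heme) -> complex(p(HGNC:F8), p(HGNC:VWF))

UNSET ALL
SET Citation = "90000005"
SET Evidence = "VWF expression, string formation and secretion upon heme incubation of endothelial cells"
SET CellType = "endothelial cell"
SET Setting = "in vitro"
SET Dose = "up to 100 µM"
SET Route = "incubation"
a(CHEBI:heme) -> p(HGNC:VWF)

UNSET ALL
SET Citation = "90000006"
SET Evidence = "VWF secretion upon heme injection into mice"
SET Species = "10090"
SET Setting = "in vivo"
SET Dose = "3.2 µmol/kg"
SET Route = "intravenous"
a(CHEBI:heme) -> p(HGNC:VWF)

UNSET ALL
SET Citation = "90000007"
SET Evidence = "heme upregulates proteases such as MMP9 which regulate VWF digestion"
SET CellType = "endothelial cell"
SET Setting = "in vitro"
SET Dose = "up to 60 µM"
a(CHEBI:heme) -> p(HGNC:MMP9)

UNSET ALL
SET Citation = "90000008"
SET Evidence = "APC function is completely abrogated upon direct heme binding"
SET Setting = "in vitro"
SET Dose = "up to 100 µM"
SET KD = "400 nM"
complex(a(CHEBI:heme), p(HGNC:PROC)) =| act(p(HGNC:PROC))

UNSET ALL
SET Citation = "90000009"
SET Evidence = "heme induces tissue factor expression in endothelial cells and leukocytes"
SET CellType = "endothelial cell"
SET Setting = "in vitro"
SET Dose = "up to 100 µM"
a(CHEBI:heme) -> p(HGNC:F3)

UNSET ALL
SET Citation = "90000010"
SET Evidence = "TF-dependent coagulation activation upon intravenous heme injection in mice"
SET Species = "10090"
SET Setting = "in vivo"
SET Dose = "100 µmol/kg"
SET Route = "intravenous"
a(CHEBI:heme) -> p(HGNC:F3)

UNSET ALL
SET Citation = "90000011"
SET Evidence = "functionally active TF ex vivo in blood exposed to heme"
SET Setting = "ex vivo"
SET Dose = "30 µM"
a(CHEBI:heme) -> p(HGNC:F3)

UNSET ALL
SET Citation = "90000012"
SET Evidence = "heme abolishes the prothrombinase-catalyzed reaction via inhibition of FVa"
SET Setting = "in_vivo"
SET Dose = "4 mg/kg"
a(CHEBI:heme) -| act(p(HGNC:F5))

UNSET ALL
SET Citation = "90000013"
SET Evidence = "strong heme binding to thrombin suggested; amidolytic inhibition not reproduced"
SET Setting = "in vitro"
a(CHEBI:heme) -- act(p(HGNC:F2))

UNSET ALL
SET Citation = "90000014"
SET Evidence = "fibrinogen binds heme; fibrinogen binding to platelets and polymer formation"
SET Setting = "in vitro"
SET Dose = "up to 500 µM"
SET KD = "3.3 µM"
complex(a(CHEBI:heme), p(HGNC:FGA)) -> bp(GO:"platelet aggregation")

UNSET ALL
SET Citation = "90000014"
SET Evidence = "heme-driven fibrin crosslinking and polymer formation in plasma"
SET Setting = "in vitro"
SET Dose = "up to 500 µM"
a(CHEBI:heme) -> a(TEXT:fibrin)

UNSET ALL
SET Citation = "90000015"
SET Evidence = "GPVI binds heme with low affinity; platelet aggregation upon heme exposure"
SET CellType = "platelet"
SET Setting = "in vitro"
SET Dose = "up to 115 µM"
SET KD = "29.4 µM"
complex(a(CHEBI:heme), p(HGNC:GP6)) -> bp(GO:"platelet activation")

UNSET ALL
SET Citation = "90000016"
SET Evidence = "Syk phosphorylation in platelets upon heme exposure"
SET CellType = "platelet"
SET Setting = "in vitro"
SET Dose = "up to 50 µM"
a(CHEBI:heme) -> act(p(HGNC:SYK))

UNSET ALL
SET Citation = "90000016"
SET Evidence = "PLCgamma2 phosphorylation associated with heme exposure"
SET CellType = "platelet"
SET Setting = "in vitro"
a(CHEBI:heme) -> act(p(HGNC:PLCG2))

UNSET ALL
SET Citation = "90000017"
SET Evidence = "Akt phosphorylation in platelets upon incubation with heme"
SET CellType = "platelet"
SET Setting = "in vitro"
SET Dose = "2.5 µM"
SET Route = "incubation"
a(CHEBI:heme) -> act(p(HGNC:AKT1))

UNSET ALL
SET Citation = "90000018"
SET Evidence = "eNOS activation downstream of Akt in platelets; NO production influenced by heme"
SET CellType = "platelet"
a(CHEBI:heme) reg p(HGNC:NOS3)

UNSET ALL
SET Citation = "90000019"
SET Evidence = "PKC activation in neutrophils in the presence of heme"
SET CellType = "neutrophil"
SET Setting = "in vitro"
SET Dose = "up to 20 µM"
a(CHEBI:heme) -> act(p(HGNC:PRKCA))

UNSET ALL
SET Citation = "90000020"
SET Evidence = "heme-triggered endothelial collagen expression with increased platelet aggregation"
SET Setting = "ex vivo"
SET Dose = "1 mM"
a(CHEBI:heme) -> a(TEXT:collagen)

UNSET ALL
SET Citation = "90000021"
SET Evidence = "heme-induced fibrinogen binding to platelets proposes alphaIIb-beta3 communication"
SET CellType = "platelet"
SET Setting = "in vitro"
a(CHEBI:heme) -> complex(p(HGNC:ITGA2B), p(HGNC:ITGB3))

UNSET ALL
SET Citation = "90000021"
SET Evidence = "platelet aggregation through fibrinogen binding under heme excess"
SET CellType = "platelet"
SET Setting = "in vitro"
SET Dose = "11 µM"
a(CHEBI:heme) -> bp(GO:"platelet aggregation")

UNSET ALL
SET Citation = "90000022"
SET Evidence = "CLEC2 activation by heme associated with Syk and PLCgamma2 phosphorylation"
SET CellType = "platelet"
a(CHEBI:heme) -> act(p(HGNC:CLEC1B))

UNSET ALL
SET Citation = "90000023"
SET Evidence = "heme-triggered platelet activation along with Akt phosphorylation is TLR4-dependent"
SET CellType = "platelet"
a(CHEBI:heme) -> act(p(HGNC:TLR4))

UNSET ALL
SET Citation = "90000024"
SET Evidence = "thrombophlebitis observed upon heme administration"
SET Setting = "in vivo"
a(CHEBI:heme) -> path(MESH:Thrombophlebitis)

UNSET ALL
SET Citation = "90000025"
SET Evidence = "interrelation of heme with thromboxane A2 in platelets"
SET CellType = "platelet"
SET Setting = "in vitro"
a(CHEBI:heme) reg a(CHEBI:"thromboxane A2")
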