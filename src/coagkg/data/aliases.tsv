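# common-name <-> gene-symbol alias table for overlap matching.
# Upper-case canonical values are HGNC symbols; lower-case values are the
# canonical case-folded names of non-protein entities.  Context: blood
# coagulation / platelet activation; e.g. "tf" here is tissue factor (F3),
# not transferrin.
alias	canonical
apc	PROC
activated protein c	PROC
protein c	PROC
thrombin	F2
prothrombin	F2
tissue factor	F3
tf	F3
fibrinogen	FGA
fg	FGA
fviii	F8
fviiia	F8
factor viii	F8
fv	F5
fva	F5
factor v	F5
fix	F9
fixa	F9
factor ix	F9
fx	F10
fxa	F10
factor x	F10
fxi	F11
fxia	F11
factor xi	F11
fxii	F12
fxiia	F12
factor xii	F12
fxiii	F13A1
fxiiia	F13A1
factor xiii	F13A1
plasma kallikrein	KLKB1
kallikrein	KLKB1
von willebrand factor	VWF
gpvi	GP6
glycoprotein vi	GP6
gpv	GP5
glycoprotein v	GP5
akt	AKT1
nos	NOS3
enos	NOS3
pkc	PRKCA
plcgamma2	PLCG2
csrc	SRC
c-src	SRC
myosin	MYH9
pi3k	PIK3CA
fcrgamma	FCER1G
fcrg	FCER1G
erk	MAPK1
erk1/2	MAPK1
clec2	CLEC1B
thrombomodulin	THBD
antithrombin	SERPINC1
txa2	thromboxane a2
thromboxane a2	thromboxane a2
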