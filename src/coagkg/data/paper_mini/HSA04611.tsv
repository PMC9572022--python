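source	interaction	target	source_class	target_class
collagen	activation	GP6	metabolite	protein
GP6	binding	FCER1G	protein	protein
FCER1G	activation	SYK	protein	protein
SYK	activation	PLCG2	protein	protein
SYK	activation	PIK3CA	protein	protein
SYK	binding	LCP2	protein	protein
SYK	activation	BTK	protein	protein
BTK	activation	PLCG2	protein	protein
PIK3CA	activation	AKT1	protein	protein
AKT1	activation	NOS3	protein	protein
NOS3	activation	PRKG1	protein	protein
PLCG2	activation	PRKCA	protein	protein
PLCG2	activation	RASGRP1	protein	protein
RASGRP1	activation	RAP1A	protein	protein
RAP1A	activation	ITGB3	protein	protein
PRKCA	activation	platelet aggregation	protein	process
PRKCA	activation	MYH9	protein	protein
MYH9	activation	platelet shape change	protein	process
VWF	binding	GP1BA	protein	protein
GP1BA	binding	GP5	protein	protein
GP1BA	binding	GP9	protein	protein
ITGA2B	binding	ITGB3	protein	protein
FGA	binding	ITGA2B	protein	protein
ITGB3	activation	SRC	protein	protein
SRC	activation	SYK	protein	protein
SRC	activation	MAPK1	protein	protein
ADP	activation	P2RY12	metabolite	protein
ADP	activation	P2RY1	metabolite	protein
PTGS1	activation	TXA2	protein	metabolite
TBXAS1	activation	TXA2	protein	metabolite
TXA2	activation	TBXA2R	metabolite	protein
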