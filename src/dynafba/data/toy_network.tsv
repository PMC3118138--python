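metabolite_id	name	compartment	formula	mw	extracellular
glc	glucose	e	C6H12O6	180	1
fru	fructose	e	C6H12O6	180	1
nh4	ammonia	e	NH3	17	1
aa	amino acid pool	e	C2H5NO2	75	1
etoh	ethanol	e	C2H6O	46	1
glyc	glycerol	e	C3H8O3	92	1
ac	acetate	e	C2H4O2	60	1
succ	succinate	e	C4H6O4	118	1
co2	carbon dioxide	e	CO2	44	1
actn	acetoin	e	C4H8O2	88	1
btd	2,3-butanediol	e	C4H10O2	90	1
sterol_e	sterol (medium)	e	C6H10O	98	1
h2o	water	e	H2O	18	1
h	proton	e	H	1	1
o2	oxygen	e	O2	32	1
pyr	pyruvate	c	C3H4O3		
acald	acetaldehyde	c	C2H4O		
oaa	oxaloacetate	c	C4H4O5		
akg	2-oxoglutarate	c	C5H6O5		
mal	malate	c	C4H6O5		
fum	fumarate	c	C4H4O4		
sterol_c	sterol (cell)	c	C6H10O		
atp	ATP	c	C10H16N5O13P3		
adp	ADP	c	C10H15N5O10P2		
pi	phosphate	c	H3PO4		
nad	NAD+	c	C21H27N7O14P2		
nadh	NADH	c	C21H28N7O14P2		
fad	FAD	c	C27H33N9O15P2		
fadh2	FADH2	c	C27H35N9O15P2		
carbU	carbohydrate unit	c	C6H10O5		
protU	protein unit	c	C2H3NO		
lipU	lipid unit	c	C5H8O		
nucU	nucleotide unit	c	C8H10N4O5		

reaction_id	name	equation	lb	ub	genes	tags
EX_glc	glc exchange	glc -> 	-1000	0		exchange,hexose_uptake
EX_fru	fru exchange	fru -> 	-1000	0		exchange,hexose_uptake
EX_nh4	nh4 exchange	nh4 -> 	-1000	0		exchange,nitrogen_uptake
EX_aa	aa exchange	aa -> 	-1000	0		exchange,nitrogen_uptake
EX_etoh	etoh exchange	etoh -> 	0	1000		exchange
EX_glyc	glyc exchange	glyc -> 	0	1000		exchange
EX_ac	ac exchange	ac <-> 	-1000	0.050000000000000003		exchange
EX_succ	succ exchange	succ -> 	0	0.002		exchange
EX_co2	co2 exchange	co2 -> 	0	1000		exchange
EX_actn	actn exchange	actn -> 	0	1000		exchange
EX_btd	btd exchange	btd -> 	0	1000		exchange
EX_sterol	sterol_e exchange	sterol_e -> 	-1000	0		exchange
EX_h2o	h2o exchange	h2o <-> 	-1000	1000		exchange
EX_h	h exchange	h <-> 	-1000	1000		exchange
EX_o2	o2 exchange	o2 <-> 	-1000	1000		exchange,oxygen_uptake
GLYCO	glycolysis (lumped)	glc + 2 adp + 2 pi + 2 nad -> 2 pyr + 2 atp + 2 nadh + 2 h + 2 h2o	0	1000		
FRUISO	fructose isomerization	fru -> glc	0	1000		
PDC	pyruvate decarboxylase	pyr -> acald + co2	0	1000		
ADH	alcohol dehydrogenase	acald + nadh + h -> etoh + nad	0	1000		
ALD	acetaldehyde dehydrogenase	acald + nad + h2o -> ac + nadh + h	0	1000		
GPD	glycerol branch (lumped)	glc + 2 atp + 2 nadh + 2 h + 2 h2o -> 2 glyc + 2 adp + 2 pi + 2 nad	0	1000	GPD1 or GPD2	
ATPM	maintenance (ATP hydrolysis + turnover oxidation)	atp + 1.0600000000000001 h2o + 0.01 glc + 0.12 nad -> adp + pi + 0.059999999999999998 co2 + 0.12 nadh + 0.12 h	0	1000		maintenance_atp
ATPSLIP	uncoupled ATP hydrolysis	atp + h2o -> adp + pi	0	1000		
CARBS	storage carbohydrate synthesis	glc + atp -> carbU + adp + pi	0	1000		
PROTS	protein synthesis	aa + 2 atp + h2o -> protU + 2 adp + 2 pi	0	1000		
AAS	amino acid synthesis	0.5 glc + nh4 + h2o + 2 nad -> aa + co2 + 2 nadh + 4 h	0	1000		
LIPS	lipid synthesis	glc + nadh + h + 2 atp -> lipU + co2 + nad + h2o + 2 adp + 2 pi	0	1000		
NUCS	nucleotide synthesis	1.5 glc + 4 nh4 + 8 nad + 6 atp + 4 h2o -> nucU + co2 + 8 nadh + 8 h + 6 adp + 6 pi	0	1000		
ACTNS	acetoin synthase	2 pyr -> actn + 2 co2	0	0.050000000000000003		
BDH	butanediol dehydrogenase	actn + nadh + h -> btd + nad	0	1000		
STEROLS	sterol synthesis (O2-dependent)	glc + 5 nadh + 5 h + 0.5 o2 -> sterol_c + 5 nad + 6 h2o	0	1000		
STEROLt	sterol uptake	sterol_e -> sterol_c	0	0		sterol_uptake
PYC	pyruvate carboxylase	pyr + co2 + atp + h2o -> oaa + adp + pi	0	1000		
TCAOX1	oxidative branch to 2-oxoglutarate	pyr + oaa + 2 nad + h2o <-> akg + 2 co2 + 2 nadh + 2 h	-1000	1000		
SCL	2-oxoglutarate <-> succinate (succinyl-CoA ligase lump)	akg + nad + adp + pi <-> succ + co2 + nadh + h + atp	-1000	1000	LSC1 and LSC2	tca_oxidative_break
SDH	succinate dehydrogenase	succ + fad <-> fum + fadh2	-1000	1000	SDH1 and SDH2	tca_oxidative_break
FUMR	fumarase	mal <-> fum + h2o	-1000	1000		
MDH	malate dehydrogenase	oaa + nadh + h <-> mal + nad	-1000	1000		
FRD	fumarate reductase (NADH-linked, reductive branch)	fum + nadh + h -> succ + nad	0	1000		
QNADH	quinone-mediated NADH reoxidation	nadh -> nad + h	0	1000		quinone
QFADH	quinone-mediated FADH2 reoxidation	fadh2 -> fad + 2 h	0	1000		quinone
RESPN	NADH oxidase + oxidative phosphorylation	nadh + h + 0.5 o2 + 1.5 adp + 1.5 pi -> nad + 2.5 h2o + 1.5 atp	0	1000		
RESPF	FADH2 oxidase + oxidative phosphorylation	fadh2 + 0.5 o2 + adp + pi -> fad + 2 h2o + atp	0	1000		
BIOMASS	biomass synthesis	8.097165991902834 protU + 0.051020408163265307 sterol_c + 1.0393772893772892 lipU + 0.81055308328035591 nucU + 1.5432098765432098 carbU + 60 atp + 60 h2o -> 60 adp + 60 pi	0	1000		biomass
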