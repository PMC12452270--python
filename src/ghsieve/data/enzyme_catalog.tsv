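enzyme_type	ec_number	alternative_name
CELLULASE	EC3.2.1.4	cellulase
CELLULASE	EC3.2.1.4	avicelase
CELLULASE	EC3.2.1.4	beta-1,4-endoglucan hydrolase
CELLULASE	EC3.2.1.4	beta-1,4-glucanase
CELLULASE	EC3.2.1.4	carboxymethyl cellulase
CELLULASE	EC3.2.1.4	celludextrinase
CELLULASE	EC3.2.1.4	endo-1,4-beta-D-glucanase
CELLULASE	EC3.2.1.4	endo-1,4-beta-D-glucanohydrolase
CELLULASE	EC3.2.1.4	endo-1,4-beta-glucanase
CELLULASE	EC3.2.1.4	endoglucanase
CELLULASE	EC3.2.1.6	endo-1,4-beta-glucanase
CELLULASE	EC3.2.1.21	beta-glucosidase
CELLULASE	EC3.2.1.21	beta-D-glucoside glucohydrolase
CELLULASE	EC3.2.1.21	cellobiase
CELLULASE	EC3.2.1.74	glucan 1,4-beta-glucosidase
CELLULASE	EC3.2.1.74	1,4-beta-D-glucan glucohydrolase
CELLULASE	EC3.2.1.74	exo-1,4-beta-D-glucosidase
CELLULASE	EC3.2.1.74	exo-1,4-beta-glucanase
CELLULASE	EC3.2.1.74	exo-1,4-beta-glucosidase
CELLULASE	EC3.2.1.91	cellulose 1,4-beta-cellobiosidase
CELLULASE	EC3.2.1.91	1,4-beta-cellobiohydrolase
CELLULASE	EC3.2.1.91	4-beta-D-glucan cellobiohydrolase
CELLULASE	EC3.2.1.91	avicelase
CELLULASE	EC3.2.1.91	exo-1,4-beta-D-glucanase
CELLULASE	EC3.2.1.91	exocellobiohydrolase
CELLULASE	EC3.2.1.91	exoglucanase
CELLULASE	EC3.2.1.176	cellulose 1,4-beta-cellobiosidase
CELLULASE	EC3.2.1.176	cellulase SS
CELLULASE	EC3.2.1.176	endoglucanase SS
CELLULASE	EC3.2.1.203	carboxymethylcellulase
CELLULASE	EC3.2.1.203	CMCase
XYLANASE	EC3.2.1.8	endo-1,4-beta-xylanase
XYLANASE	EC3.2.1.37	xylan 1,4-beta-xylosidase
XYLANASE	EC3.2.1.37	1,4-beta-D-xylan xylohydrolase
XYLANASE	EC3.2.1.37	beta-xylosidase
XYLANASE	EC3.2.1.37	exo-1,4-beta-xylosidase
XYLANASE	EC3.2.1.37	xylobiase
XYLANASE	EC3.2.1.156	oligosaccharide reducing-end xylanase
XYLANASE	EC3.2.1.156	reducing end xylose-releasing exo-oligoxylanase
XYLANASE	EC3.2.1.156	Rex
PECTINASE	EC3.2.1.15	endo-polygalacturonase
PECTINASE	EC3.2.1.15	pectinase
PECTINASE	EC3.2.1.15	pectin depolymerase
PECTINASE	EC3.2.1.15	polygalacturonase
CHITINASE	EC3.2.1.14	chitinase
CHITINASE	EC3.2.1.14	1,4-beta-poly-N-acetylglucosaminidase
CHITINASE	EC3.2.1.14	chitodextrinase
CHITINASE	EC3.2.1.14	poly-beta-glucosaminidase
MANNANASE	EC3.2.1.25	beta-mannosidase
MANNANASE	EC3.2.1.25	mannanase
MANNANASE	EC3.2.1.25	mannase
MANNANASE	EC3.2.1.78	mannan endo-1,4-beta-mannosidase
MANNANASE	EC3.2.1.78	beta-mannanase
MANNANASE	EC3.2.1.78	endo-1,4-mannanase
FUCOSIDASE	EC3.2.1.51	alpha-L-fucosidase
FUCOSIDASE	EC3.2.1.51	Alpha-L-fucoside fucohydrolase
FUCOSIDASE	EC3.2.1.212	endo-(1,4)-fucoidanase
FUCOSIDASE	EC3.2.1.212	alpha-L-fucosidase
FUCOSIDASE	EC3.2.1.212	poly(1,4-alpha-L-fucoside-2/3-sulfate) glycanohydrolase
LAMINARINASE	EC3.2.1.39	glucan endo-1,3-beta-D-glucosidase
LAMINARINASE	EC3.2.1.39	(1,3)-beta-glucan endohydrolase
LAMINARINASE	EC3.2.1.39	endo-1,3-beta-glucanase
LAMINARINASE	EC3.2.1.39	laminarinase
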