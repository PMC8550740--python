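host_scientific	host_common	host_family	SSA1-SG1	SSA1-SG2	SSA1-SG3	SSA2	SSA6	SSA9	SSA10	SSA11	SSA12	SSA13	MED-ASL	MED-Q1	MEAM1	MEAM2	IO	EA1	B. Uganda1	SSA14	SSA15	SSA16	B. Uganda2	B. Uganda3	B. Uganda4	B. Uganda5
Abelmoschus esculentus	Okra	Malvaceae	0	0	0	0	0	0	0	0	0	0	6	0	0	0	0	0	0	0	0	0	0	0	0	0
Ageratum conzyoides	Goatweed	Asteraceae	1	0	0	0	0	2	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
Ageratum sp.	Goatweed-like	Asteraceae	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Amaranthus spinosus	Pigweed	Amaranthaceae	1	0	0	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0
Arachis hypogaea	Peanut	Fabaceae	0	1	0	0	0	0	0	0	0	0	2	0	0	0	0	0	1	0	0	0	0	0	0	0
Aspilia africana	Haemorrhage plant	Asteraceae	1	0	0	0	3	0	0	0	0	0	7	0	1	0	0	0	1	0	0	0	0	0	0	0
Bidens pilosa	Black jack	Asteraceae	0	1	0	0	0	0	0	0	0	0	1	0	1	0	0	0	3	0	0	0	0	0	0	0
Bothriocline tomentosa	Luwelewele	Asteraceae	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	1	0	0	1	0	0	0	0
Brassica oleracea	Cabbage	Brassicaceae	0	0	0	0	0	0	0	0	0	0	3	0	3	0	0	0	2	0	0	0	0	0	0	0
Brassica sp.	Collard/Sukumawiki	Brassicaceae	0	0	0	0	0	0	0	0	0	0	0	0	3	0	0	0	0	0	0	0	0	0	0	0
Cannabis sativa	Marijuana	Cannabiaceae	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
Capsicum annuum	Hot pepper	Solanaceae	1	1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
Carica papaya	Papaya	Caricaceae	0	2	0	0	0	0	0	0	0	0	0	1	0	0	1	0	2	0	0	0	0	0	0	0
Conyza sumatrensis	White horseweed	Asteraceae	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	5	0	0	0	0	0	0	0
Crassocephalum crepidioides	Fireweed	Asteraceae	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0
Cucurbita moschata	Pumpkin	Cucurbitaceae	4	1	1	0	0	3	0	0	0	1	55	0	2	0	2	1	0	0	1	0	0	0	0	0
Dichrocephala integrifolia	Bicolor buttonweed	Asteraceae	1	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	1
Emilia coccinea	Scarlet tasselflower	Asteraceae	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0
Eputoni (local name)	Eputoni	Unknown	0	0	0	1	0	0	0	0	0	0	1	2	0	0	0	0	0	0	0	0	0	0	0	0
Erlangea tomentosa	Ekitokotoko	Asteraceae	0	0	0	0	0	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
Erythrina abyssinica	Red hot poker tree	Fabaceae	3	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	1	0	0
Etakari (local name)	Etakari	Unknown	0	0	0	0	0	0	0	0	0	0	3	0	0	0	0	0	0	0	0	0	0	0	0	0
Gossypium herbaceum	Cotton	Malvaceae	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	1	0	0	0	0	0	0	0
Helianthus annuus	Sunflower	Asteraceae	2	0	0	0	0	0	1	0	0	0	6	0	0	0	0	0	0	0	0	0	0	0	0	0
Hoslundia opposite	Orange bird berry	Lamiaceae	0	0	1	0	0	1	2	0	0	0	4	0	0	0	0	0	0	0	0	0	0	0	1	0
Ipomoea batatas	Sweet potato	Convolvulaceae	1	0	1	0	1	0	0	0	0	0	38	0	0	0	0	1	37	0	0	0	0	0	1	0
Jatropha gossypifolia	Bellyache bush	Euphorbiaceae	5	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Kabowabowa (local name)	Kabowabowa	Unknown	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0
Kigombolola (Local name)	Kigombolola	Unknown	0	0	0	0	0	0	0	0	0	3	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Lantana camara	Tickberry	Verbenaceae	0	0	0	1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
Leonotis nepetaefolia	Lion's ear	Lamiaceae	0	2	0	0	0	1	0	1	0	1	0	0	0	0	0	0	0	0	0	1	0	0	0	0
Luyamayama (local name)	Luyamayama	Unknown	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0
Manihot esculenta	Cassava	Euphorbiaceae	63	6	0	29	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Manihot glaziovii	Tree cassava	Euphorbiaceae	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0
Microglossa pyrifolia	Kafungankadde	Asteraceae	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
Mimosa sp.	Temba	Fabaceae	1	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Nicotiana rustica	Aztec tobacco	Solanaceae	3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Nicotiana tabacum	Tobacco	Solanaceae	0	1	2	0	0	0	0	0	0	0	1	26	2	0	0	0	3	0	0	0	0	0	0	0
Njoka etaruma (local name)	Njoka etaruma	Unknown	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0
Ocimum gratissimum	African basil	Lamiaceae	1	0	3	1	70	0	0	0	0	2	8	0	0	0	0	0	0	0	0	0	0	0	0	0
Oxygonum sinuatum	Kafumitabagenda	Polygonaceae	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0
Phaseolus vulgaris	Common bean	Fabaceae	11	1	5	1	0	1	1	0	0	1	6	0	0	0	2	1	11	0	0	0	1	2	0	0
Ribes uva-crispa	Gooseberry	Grossulariaceae	0	0	0	0	0	0	0	0	0	2	1	0	0	0	1	0	2	0	0	0	0	0	0	0
Rotheca myricoides	Butterfly bush	Lamiaceae	1	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Senna occidentalis	Coffee senna	Fabaceae	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0
Senna sp.	Magele ga nkoko	Fabaceae	1	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0
Sesamum indicum	Sesame	Pedaliaceae	2	0	0	0	1	0	0	0	0	0	8	0	0	0	0	0	1	0	0	0	0	0	0	0
Sida acuta	Wireweed	Malvaceae	0	3	3	0	1	2	0	0	0	3	48	6	1	0	1	0	2	0	0	0	0	0	0	0
Solanum aethiopicum	Bitter tomato	Solanaceae	1	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0	0	0
Solanum incanum	Nightshade	Solanaceae	2	0	0	0	0	0	0	0	0	0	5	1	1	0	0	0	0	1	0	0	0	0	0	0
Solanum lycopersicum	Tomato	Solanaceae	4	2	0	2	1	6	0	0	0	2	14	1	7	0	3	1	8	0	0	0	0	0	0	0
Solanum melongena	Eggplant	Solanaceae	1	0	5	0	0	3	1	1	0	2	9	1	10	1	1	0	3	0	0	0	0	0	0	0
Solanum nigrum	Black nightshade	Solanaceae	0	0	0	0	0	0	0	0	0	2	3	0	0	0	0	0	3	0	0	0	0	0	0	0
Spathodea campanulata	African tuliptree	Bignoniaceae	0	1	0	0	0	0	0	0	0	0	1	0	0	0	1	0	0	0	0	0	0	0	0	0
Striga hermonthica	Giant witchweed	Orobanchaceae	1	0	0	1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
Tithonia diversifolia	Tree marigold	Asteraceae	0	0	2	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Toovu (local name)	Toovu	Unknown	1	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Vigna unguiculata	Cowpea	Fabaceae	4	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Unknowns	Unknowns	Unknown	17	2	5	0	2	2	3	0	2	4	22	9	6	0	1	0	9	0	0	0	0	1	0	0
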