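species	event_id	exclude_flag
Medicago_truncatula	faboideae	0
Cicer_arietinum	faboideae	0
Lotus_japonicus	faboideae	0
Cajanus_cajan	faboideae	0
Glycine_max	glycine	0
Arabidopsis_thaliana	brassicaceae_alpha	0
Arabidopsis_lyrata	brassicaceae_alpha	0
Capsella_rubella	brassicaceae_alpha	0
Thellungiella_parvula	brassicaceae_alpha	0
Arabidopsis_thaliana_beta	brassicaceae_beta	0
Brassica_rapa	brassica_triplication	0
Gossypium_raimondii	gossypium	0
Populus_trichocarpa	salicoid	0
Manihot_esculenta	manihot	0
Linum_usitatissimum	linum	0
Malus_domestica	maleae	0
Pyrus_bretschneideri	maleae	0
Solanum_lycopersicum	solanaceae_triplication	0
Solanum_tuberosum	solanaceae_triplication	0
Mimulus_guttatus	mimulus	0
Musa_acuminata	musa	1
Zea_mays	zea	0
Oryza_sativa	grass_rho	0
Sorghum_bicolor	grass_rho	0
Brachypodium_distachyon	grass_rho	0
Setaria_italica	grass_rho	0
Nelumbo_nucifera	nelumbo	0
Nuphar_advena	nuphar	0
Eschscholzia_californica	eschscholzia	0
Physcomitrella_patens	physcomitrella	0
Utricularia_gibba	utricularia	0
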