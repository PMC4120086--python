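species	event_id	source	age	ci_low	ci_high
Medicago_truncatula		anchor	66.01		
Cicer_arietinum		anchor	63.66		
Lotus_japonicus		anchor	63.26		
Cajanus_cajan		anchor	56.96		
Glycine_max		anchor	13.0		
Arabidopsis_thaliana		anchor	38.0		
Arabidopsis_lyrata		anchor	40.0		
Capsella_rubella		anchor	42.0		
Thellungiella_parvula		peak_based	41.0		
Arabidopsis_thaliana_beta		anchor	64.0		
Brassica_rapa		anchor	15.9		
Gossypium_raimondii		anchor	16.6		
Populus_trichocarpa		anchor	34.7		
Manihot_esculenta		anchor	47.0		
Linum_usitatissimum		anchor	6.8		
Malus_domestica		anchor	18.32		
Pyrus_bretschneideri		anchor	19.85		
Solanum_lycopersicum		anchor	63.0		
Solanum_tuberosum		anchor	67.0		
Mimulus_guttatus		peak_based	46.0		
Musa_acuminata		anchor	63.0		
Zea_mays		anchor	11.9		
Oryza_sativa		anchor	95.0		
Sorghum_bicolor		anchor	96.0		
Brachypodium_distachyon		anchor	94.0		
Setaria_italica		anchor	97.0		
Nelumbo_nucifera		peak_based	65.5		
Nuphar_advena		peak_based	64.0		
Eschscholzia_californica		peak_based	63.0		
Physcomitrella_patens		peak_based	65.0		
Utricularia_gibba		peak_based	15.0		
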