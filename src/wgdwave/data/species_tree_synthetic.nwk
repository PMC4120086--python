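(Physcomitrella_patens:450,(Selaginella_moellendorffii:410,(Nuphar_advena:140,((Acorus_americanus:125,(Phoenix_dactylifera:110,(Musa_acuminata:100,((Oryza_sativa:47,Brachypodium_distachyon:47):23,(Setaria_italica:45,(Sorghum_bicolor:12,Zea_mays:12):33):25):30):10):15):10,(Eschscholzia_californica:130,(Nelumbo_nucifera:120,(Vitis_vinifera:118,(((Solanum_lycopersicum:7,Solanum_tuberosum:7):78,(Mimulus_guttatus:70,Utricularia_gibba:70):15):30,(((Carica_papaya:70,(((Arabidopsis_thaliana:10,Arabidopsis_lyrata:10):3,Capsella_rubella:13):17,(Thellungiella_parvula:20,Brassica_rapa:20):10):40):30,((Gossypium_raimondii:60,Theobroma_cacao:60):35,(Citrus_sinensis:90,Eucalyptus_grandis:90):5):5):8,((Linum_usitatissimum:90,(Populus_trichocarpa:75,Manihot_esculenta:75):15):15,((((Medicago_truncatula:18,Cicer_arietinum:18):32,Lotus_japonicus:50):5,(Glycine_max:25,Cajanus_cajan:25):30):45,(Cucumis_sativus:98,(Fragaria_vesca:90,(Prunus_persica:60,(Malus_domestica:15,Pyrus_bretschneideri:15):45):30):8):2):5):3):7):3):2):10):5):5):270):40);
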