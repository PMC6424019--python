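specimen,species,superorder,size_cm,size_kind,raphe_type,organ_width_mm,organ_length_mm,area_largest_mm2,rel_area_largest,lamellar_number,gross_area_mm2,rel_gross_area,folds_area_mm2,rel_folds_area,pct_increase,pct_increase_sd,branching_index,frequency,amplitude,deviation,brinkhoff
Cm,Chimaera_monstrosa,Holocephali,52,SL,round,10,10,12.5,0.46,34,850,31,1819,67,114,8.5,1.96,0.9,0.5,0.53,0.46
Dl,Dalatias_licha,Squalomorphi,35.5,TL,elongated,7,9,7.5,0.60,44,543,43,977,78,80,10.2,1.61,0.61,0.42,0.3,0.27
Es,Etmopterus_spinax,Squalomorphi,37.5,TL,elongated,6,9,8,0.57,52,720,51,2246,160,212,39,2.16,0.98,0.66,0.45,0.61
Gm1,Galeus_melastomus,Galeomorphi,40,TL,elongated,10,14,14,0.88,38,973,61,3240,203,233,57,2.13,1,0.77,0.4,0.69
Gm3,Galeus_melastomus,Galeomorphi,14.5,TL,elongated,5,7,5.5,2.62,40,351,167,1755,835,400,31,2.2,1,0.67,0.34,0.6
Hp,Heptranchias_perlo,Squalomorphi,108,TL,round,13,13,33.5,0.29,34,2278,20,12848,110,464,38,3.29,0.95,0.8,0.52,0.72
Pg,Prionace_glauca,Galeomorphi,43,TL,elongated,8,13,16.5,0.89,95,2825,153,7821,423,177,9,2.04,0.96,0.63,0.42,0.56
Pv,Pteroplatytrygon_violacea,Batoidea,107,DW,elongated,13,26,22,0.19,110,4340,38,7378,64,70,12,1.94,0.92,0.39,0.51,0.38
Rb,Raja_brachyura,Batoidea,98.5,DW,elongated,14,28,56.2,0.58,61,6300,65,19971,206,217,30,3.67,1,0.67,0.37,0.61
Rm,Raja_miraletus,Batoidea,41,DW,elongated,10,22,17,1.01,46,1364,81,5006,298,267,29,3.42,0.89,0.72,0.39,0.59
Rp,Raja_polystigma,Batoidea,32,DW,elongated,9,15,15.1,1.47,40,1056,103,4425,432,319,32,3.52,1,0.75,0.31,0.66
Sb,Squalus_blainville,Squalomorphi,53,TL,elongated,7,12,14.1,0.50,47,1177,42,3872,138,229,21,2.03,0.94,0.68,0.49,0.62
Sc7,Scyliorhinus_canicula,Galeomorphi,21,TL,elongated,6,8,7.6,1.72,34,453,103,1586,360,250,37,2.09,0.87,0.69,0.28,0.54
Sc8,Scyliorhinus_canicula,Galeomorphi,35.5,TL,elongated,8,12,13,1.03,34,730,58,3249,258,345,53,1.99,0.98,0.75,0.4,0.67
Sm,Somniosus_microcephalus,Squalomorphi,230,TL,elongated,35,50,220,0.42,44,11700,22,62478,118,434,93,6.92,0.99,0.8,0.36,0.7
Sr,Somniosus_rostratus,Squalomorphi,96,TL,elongated,14,23,44,0.48,36,2200,24,13090,142,495,35,7.9,1,0.82,0.46,0.74
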