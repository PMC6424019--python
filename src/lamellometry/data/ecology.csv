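species,habitat,teleost_pct,mollusc_pct,crustacean_pct,chondrichthyan_pct,echinoderm_pct
Chimaera_monstrosa,bathydemersal,,,20,,70
Dalatias_licha,bathydemersal,40,15,20,25,
Etmopterus_spinax,bathydemersal,85,,15,,
Galeus_melastomus,bathydemersal,20,40,40,,
Heptranchias_perlo,bathydemersal,75,20,5,,
Prionace_glauca,pelagic-oceanic,60,40,,,
Pteroplatytrygon_violacea,pelagic-oceanic,95,5,,,
Raja_brachyura,demersal,95,5,,,
Raja_miraletus,demersal,2,2,95,,
Raja_polystigma,demersal,10,,80,,
Scyliorhinus_canicula,demersal,12,6,75,,
Somniosus_microcephalus,benthopelagic,65,20,,5,
Somniosus_rostratus,bathydemersal,,95,5,,
Squalus_blainville,demersal,20,11,52,,
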