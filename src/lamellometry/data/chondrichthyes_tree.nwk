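(Chimaera_monstrosa,(((Raja_brachyura,Raja_polystigma,Raja_miraletus),Pteroplatytrygon_violacea),((Heptranchias_perlo,(Squalus_blainville,(Dalatias_licha,(Etmopterus_spinax,(Somniosus_rostratus,Somniosus_microcephalus))))),(Scyliorhinus_canicula,(Galeus_melastomus,Prionace_glauca)))));
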