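species,stems_per_m2,isv_over_dc,rar,rar_fine,t_max,rar_coarse,ei,eps_ult_mech,eps_ult_phys,n_concentration,cellulose
Agave americana,1,2,3,1,2,3,3,3,2,1,2
Artemisia codonocephala,2,2,2,3,3,1,2,3,2,3,3
Arthraxon hispidus,3,2,1,3,2,1,1,1,2,1,1
Bauhinia championii,1,3,2,2,2,2,2,1,2,2,1
Chloris anomala,3,1,1,3,3,1,1,3,2,1,3
Ficus tikoua,2,1,2,2,2,2,1,1,1,1,3
Jatropha curcas,1,2,2,1,1,3,3,3,2,1,3
Pueraria stricta,1,3,2,2,3,2,3,3,3,3,1
Rhus chinensis,2,2,2,1,1,3,3,1,2,2,1
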