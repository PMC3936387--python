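species_id,species_name,fresh_body_mass_mg,consumption_rate_mg_ind_day,consumption_sd
Pm,Philoscia muscorum,10.22,0.20,0.29
Ps,Porcellio scaber,43.55,1.66,0.29
Oa,Oniscus asellus,64.65,0.87,0.56
Av,Armadillidium vulgare,67.64,1.80,0.56
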