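population_id,order,family,genus,species,realm,site_area_km2,body_mass_kg,method,camera_analysis,tissue,n_individuals
marten_site1,Carnivora,Mustelidae,Martes,Martes americana,nearctic,12.5,1.0,live_trap,none,none,18
marten_site1,Carnivora,Mustelidae,Martes,Martes americana,nearctic,12.5,1.0,genetic,none,hair,21
bobcat_site1,Carnivora,Felidae,Lynx,Lynx rufus,nearctic,140.0,9.0,live_trap,none,none,9
bobcat_site1,Carnivora,Felidae,Lynx,Lynx rufus,nearctic,140.0,9.0,camera,spatial,none,14
badger_site1,Carnivora,Mustelidae,Meles,Meles meles,palearctic,25.0,12.0,camera,random,none,11
badger_site1,Carnivora,Mustelidae,Meles,Meles meles,palearctic,25.0,12.0,genetic,none,scat,16.25
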