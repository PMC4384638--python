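species,cd33rsiglec_count,klk_count,tlr_count,fcgr_count,max_lifespan_years,body_weight_grams
Homo_sapiens,10,15,10,5,122.5,62035
Pan_troglodytes,9,15,10,4,59.4,44984
Pongo_abelii,8,14,11,4,59.0,61000
Macaca_mulatta,8,14,11,4,40.0,7800
Callithrix_jacchus,7,13,10,3,22.8,290
Mus_musculus,5,13,12,4,4.0,20.5
Rattus_norvegicus,5,14,12,4,3.8,300
Canis_familiaris,6,14,11,4,24.0,32000
Felis_catus,6,14,10,3,30.0,3900
Sus_scrofa,7,14,10,4,27.0,120000
Bos_taurus,7,15,11,4,20.0,750000
Equus_caballus,8,14,10,4,57.0,400000
Loxodonta_africana,9,14,12,4,65.5,4800000
Monodelphis_domestica,4,14,11,3,5.1,100
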