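((((((((Homo_sapiens:8,Pan_troglodytes:8):10,Pongo_abelii:18):7,Macaca_mulatta:25):15,Callithrix_jacchus:40):45,(Mus_musculus:25,Rattus_norvegicus:25):60):5,((Canis_familiaris:56,Felis_catus:56):24,(Equus_caballus:72,(Bos_taurus:60,Sus_scrofa:60):12):8):10):7,Loxodonta_africana:97):51,Monodelphis_domestica:148);
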