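((((((((Homo_sapiens:6.5,Pan_troglodytes:6.5):9.5,Pongo_abelii:16):13,Macaca_mulatta:29):14,Callithrix_jacchus:43):44,(Mus_musculus:21,Rattus_norvegicus:21):66):5,((Canis_familiaris:54,Felis_catus:54):24,(Equus_caballus:76,(Bos_taurus:62,Sus_scrofa:62):14):2):14):8,Loxodonta_africana:100):60,Monodelphis_domestica:160);
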