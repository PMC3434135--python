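((Danio_rerio:250,(Oryzias_latipes:120,(Gasterosteus_aculeatus:95,(Tetraodon_nigroviridis:50,Takifugu_rubripes:50)Tetraodontidae:45)Percomorpha:25)Euteleosteomorpha:130)Teleostei:180,(Xenopus_tropicalis:350,((Gallus_gallus:100,Taeniopygia_guttata:100)Aves:215,(Ornithorhynchus_anatinus:166,(Monodelphis_domestica:147,((Canis_familiaris:85,(Equus_caballus:78,(Bos_taurus:65,Sus_scrofa:65)Artiodactyla:13)Zooamata:7)Laurasiatheria:12,((Mus_musculus:20,Rattus_norvegicus:20)Murinae:70,(Macaca_mulatta:29,(Homo_sapiens:7,Pan_troglodytes:7)Hominini:22)Catarrhini:61)Euarchontoglires:7)Eutheria:50)Theria:19)Mammalia:149)Amniota:35)Tetrapoda:80)Osteichthyes;
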