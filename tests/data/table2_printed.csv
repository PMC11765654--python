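species,edge_canopy_prob,forest_canopy_prob,delta_edge,positive
Adelpha iphiclus,0.4545,1.0000,0.5455,1
Adelpha naxia,1.0000,1.0000,0.0000,0
Archaeoprepona demophon,0.1250,0.2500,0.1250,1
Archaeoprepona demophoon,1.0000,1.0000,0.0000,0
Archaeoprepona meander,0.0000,0.0000,0.0000,0
Caligo atreus,0.0000,0.0000,0.0000,0
Caligo brasiliensis,0.0000,0.0000,0.0000,0
Catoblepia orgetorix,0.0000,0.0400,0.0400,1
Catonephele numilia,0.1905,0.6667,0.4762,1
Catonephele orites,0.0714,0.5385,0.4670,1
Cissia confusa,0.5000,0.6000,0.1000,1
Colobura annulata,0.5000,0.7143,0.2143,1
Dryas iulia,0.0000,1.0000,1.0000,1
Dulcedo polita,0.0000,0.0370,0.0370,1
Epiphile adrasta,0.0000,1.0000,1.0000,1
Eryphanis lycomedon,0.0000,0.0000,0.0000,0
Fountainea eurypyle,0.0000,1.0000,1.0000,1
Hamadryas amphinome,1.0000,1.0000,0.0000,0
Hamadryas arinome,0.5000,0.7692,0.2692,1
Hamadryas laodamia,0.9000,1.0000,0.1000,1
Historis odius,0.5000,1.0000,0.5000,1
Magneuptychia gomezi,0.5000,0.6667,0.1667,1
Megeuptychia antonoe,1.0000,0.0000,-1.0000,0
Memphis artacaena,0.5000,1.0000,0.5000,1
Memphis cleomestra,1.0000,0.6667,-0.3333,0
Memphis mora,0.0000,1.0000,1.0000,1
Memphis moruus,0.7857,1.0000,0.2143,1
Myscelia cyaniris,0.1765,0.0000,-0.1765,0
Myscelia leucocyana,0.7500,1.0000,0.2500,1
Nessaea aglaura,0.0000,0.1944,0.1944,1
Nica flavilla,1.0000,1.0000,0.0000,0
Opsiphanes cassina,1.0000,0.8000,-0.2000,0
Pareuptychia metaleuca,0.0000,0.2500,0.2500,1
Prepona laertes,0.8889,1.0000,0.1111,1
Pyrrhogyra neaerea,0.0000,0.8333,0.8333,1
Pyrrhogyra otolais,0.5000,1.0000,0.5000,1
Taygetis thamyra,0.0000,0.0000,0.0000,0
Temenis laothoe,0.7500,0.7778,0.0278,1
Tigridia acesta,0.0000,0.3333,0.3333,1
Zaretis isidora,0.0000,0.6250,0.6250,1
Zaretis itys,0.0000,0.5000,0.5000,1
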