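species,EC,EU,FC,FU
Adelpha iphiclus,5,6,7,0
Adelpha naxia,1,0,1,0
Archaeoprepona demophon,2,14,1,3
Archaeoprepona demophoon,1,0,2,0
Archaeoprepona meander,0,2,0,1
Caligo atreus,0,4,0,20
Caligo brasiliensis,0,9,0,12
Catoblepia orgetorix,0,2,1,24
Catonephele numilia,4,17,4,2
Catonephele orites,1,13,14,12
Cissia confusa,1,1,3,2
Colobura annulata,1,1,5,2
Dryas iulia,0,4,1,0
Dulcedo polita,0,2,1,26
Epiphile adrasta,0,1,1,0
Eryphanis lycomedon,0,7,0,2
Fountainea eurypyle,0,1,1,0
Hamadryas amphinome,4,0,4,0
Hamadryas arinome,1,1,10,3
Hamadryas laodamia,9,1,12,0
Historis odius,2,2,2,0
Magneuptychia gomezi,1,1,2,1
Megeuptychia antonoe,1,0,0,1
Memphis artacaena,1,1,2,0
Memphis cleomestra,1,0,2,1
Memphis mora,0,1,1,0
Memphis moruus,11,3,3,0
Myscelia cyaniris,3,14,0,1
Myscelia leucocyana,6,2,5,0
Nessaea aglaura,0,5,7,29
Nica flavilla,1,0,1,0
Opsiphanes cassina,6,0,4,1
Pareuptychia metaleuca,0,5,1,3
Prepona laertes,16,2,7,0
Pyrrhogyra neaerea,0,1,5,1
Pyrrhogyra otolais,1,1,2,0
Taygetis thamyra,0,15,0,5
Temenis laothoe,3,1,7,2
Tigridia acesta,0,2,1,2
Zaretis isidora,0,2,5,3
Zaretis itys,0,3,7,7
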