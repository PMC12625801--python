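species,godfrey_kg,jungers_kg
Archaeolemur edwardsi,24.5,26.5
Archaeolemur majori,13.9,18.2
Megaladapis edwardsi,75.4,85.1
Megaladapis grandidieri,63.0,74.3
Megaladapis madagascariensis,38.0,46.5
Mesopropithecus globiceps,9.4,11.3
Mesopropithecus pithecoides,9.7,
Mesopropithecus dolichobrachion,,13.7
Palaeopropithecus ingens,39.5,41.5
Palaeopropithecus maximus,52.6,45.8
Babakotia radofilai,16.2,20.7
Archaeoindris fontoynontii,197.5,161.2
Pachylemur insignis,10.0,11.5
Pachylemur jullyi,12.8,13.4
Daubentonia robustus,13.5,14.2
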