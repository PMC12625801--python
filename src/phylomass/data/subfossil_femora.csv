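species,specimen_id,dataset,fcsa_mm2,published_bm_kg,published_lower95_kg,published_upper95_kg
Archaeoindris fontoynontii,L1,Jungers,708.10,127.74,56.95,286.52
Archaeolemur sp.,AN3,Jungers,142.01,16.85,7.91,35.90
Archaeolemur sp.,AN4,Jungers,139.91,16.54,7.77,35.22
Archaeolemur edwardsi,AB,Thompson,162.80,20.02,9.37,42.79
Archaeolemur edwardsi,AF,Thompson,180.30,22.77,10.63,48.80
Archaeolemur edwardsi,AH,Thompson,178.20,22.44,10.47,48.07
Archaeolemur edwardsi,BD,Thompson,160.80,19.71,9.23,42.12
Archaeolemur edwardsi,BG,Thompson,123.40,14.12,6.65,29.97
Archaeolemur edwardsi,BH,Thompson,148.00,17.76,8.33,37.86
Archaeolemur edwardsi,AE8,Jungers,168.02,20.83,9.74,44.57
Archaeolemur edwardsi,AE9,Jungers,147.15,17.63,8.27,37.58
Archaeolemur edwardsi,AE10,Jungers,175.65,22.03,10.29,47.19
Archaeolemur edwardsi,AE11,Jungers,170.41,21.21,9.91,45.38
Archaeolemur edwardsi,AE12,Jungers,163.40,20.12,9.41,43.00
Archaeolemur edwardsi,AE13,Jungers,173.64,21.72,10.14,46.49
Archaeolemur edwardsi,AE14,Jungers,168.38,20.89,9.77,44.69
Archaeolemur edwardsi,AE15,Jungers,155.58,18.91,8.86,40.37
Archaeolemur majori,AA,Thompson,120.80,13.75,6.48,29.16
Archaeolemur majori,AC,Thompson,136.40,16.02,7.53,34.09
Archaeolemur majori,AD,Thompson,93.40,9.94,4.71,20.97
Archaeolemur majori,AG,Thompson,141.00,16.70,7.84,35.57
Archaeolemur majori,AI,Thompson,122.30,13.96,6.58,29.63
Archaeolemur majori,AK,Thompson,90.70,9.58,4.54,20.20
Archaeolemur majori,AM,Thompson,108.00,11.94,5.64,25.26
Archaeolemur majori,AN,Thompson,128.40,14.84,6.99,31.54
Archaeolemur majori,AR,Thompson,100.90,10.95,5.18,23.15
Archaeolemur majori,AT,Thompson,109.20,12.10,5.72,25.62
Archaeolemur majori,AV,Thompson,124.30,14.25,6.71,30.25
Archaeolemur majori,AW,Thompson,116.40,13.12,6.19,27.81
Archaeolemur majori,BC,Thompson,119.40,13.54,6.39,28.73
Archaeolemur majori,BR,Thompson,120.00,13.63,6.43,28.92
Archaeolemur majori,AM3,Jungers,134.10,15.68,7.37,33.35
Archaeolemur majori,AM4,Jungers,110.90,12.34,5.83,26.13
Archaeolemur majori,AM5,Jungers,108.82,12.05,5.69,25.51
Babakotia radofilai,B5,Jungers,112.31,12.54,5.92,26.56
Babakotia radofilai,B6,Jungers,94.79,10.13,4.80,21.37
Babakotia radofilai,B7,Jungers,106.50,11.73,5.54,24.81
Babakotia radofilai,B8,Jungers,114.09,12.79,6.04,27.10
Daubentonia robusta,DR4,Jungers,92.44,9.81,4.65,20.69
Daubentonia robusta,DR5,Jungers,92.87,9.87,4.68,20.82
Megaladapis edwardsi,NC,Thompson,333.70,49.48,22.67,108.01
Megaladapis edwardsi,NE,Thompson,449.80,72.09,32.69,158.98
Megaladapis edwardsi,NF,Thompson,415.80,65.29,29.69,143.59
Megaladapis edwardsi,NG,Thompson,436.50,69.42,31.51,152.91
Megaladapis edwardsi,NH,Thompson,299.10,43.10,19.82,93.76
Megaladapis edwardsi,NI,Thompson,398.40,61.87,28.17,135.85
Megaladapis edwardsi,ME7,Jungers,469.75,76.15,34.48,168.18
Megaladapis edwardsi,ME8,Jungers,446.91,71.51,32.44,157.66
Megaladapis edwardsi,ME9,Jungers,448.67,71.87,32.59,158.46
Megaladapis edwardsi,ME10,Jungers,469.52,76.10,34.46,168.07
Megaladapis edwardsi,ME11,Jungers,381.38,58.55,26.71,128.39
Megaladapis edwardsi,ME12,Jungers,410.04,64.15,29.19,141.01
Megaladapis grandidieri,ND,Thompson,381.00,58.48,26.67,128.22
Megaladapis grandidieri,MGr3,Jungers,417.78,65.68,29.86,144.47
Megaladapis grandidieri,MGr4,Jungers,359.91,54.43,24.87,119.11
Megaladapis grandidieri,MGr5,Jungers,291.02,41.64,19.16,90.50
Megaladapis grandidieri,MGr6,Jungers,328.48,48.51,22.23,105.83
Megaladapis grandidieri,MGr7,Jungers,428.61,67.84,30.82,149.34
Megaladapis madagascariensis,NA,Thompson,233.00,31.46,14.58,67.91
Megaladapis madagascariensis,NB,Thompson,190.80,24.46,11.39,52.49
Megaladapis madagascariensis,MM5,Jungers,207.00,27.10,12.60,58.30
Megaladapis madagascariensis,MM6,Jungers,217.32,28.82,13.38,62.08
Megaladapis madagascariensis,MM7,Jungers,275.31,38.83,17.90,84.23
Megaladapis madagascariensis,MM8,Jungers,282.71,40.15,18.49,87.17
Megaladapis madagascariensis,MM9,Jungers,251.12,34.58,15.98,74.80
Megaladapis madagascariensis,MM10,Jungers,207.03,27.11,12.60,58.31
Mesopropithecus dolichobrachion,MD2,Jungers,79.31,8.09,3.84,17.01
Mesopropithecus globiceps,MA,Thompson,63.20,6.07,2.90,12.73
Mesopropithecus globiceps,MB,Thompson,70.60,6.98,3.33,14.66
Mesopropithecus globiceps,MC,Thompson,72.10,7.17,3.42,15.06
Mesopropithecus globiceps,MG6,Jungers,74.54,7.48,3.56,15.71
Mesopropithecus globiceps,MG7,Jungers,58.74,5.54,2.65,11.59
Mesopropithecus globiceps,MG8,Jungers,78.57,7.99,3.80,16.81
Mesopropithecus globiceps,MG9,Jungers,75.67,7.62,3.63,16.02
Mesopropithecus globiceps,MG10,Jungers,64.71,6.26,2.99,13.12
Mesopropithecus globiceps,MG11,Jungers,78.98,8.04,3.82,16.92
Mesopropithecus pithecoides,MD,Thompson,87.40,9.14,4.34,19.26
Pachylemur insignis,DA,Thompson,89.40,9.40,4.46,19.83
Pachylemur insignis,DB,Thompson,85.00,8.83,4.19,18.59
Pachylemur insignis,DC,Thompson,72.40,7.21,3.43,15.14
Pachylemur insignis,DD,Thompson,103.00,11.24,5.32,23.77
Pachylemur insignis,DE,Thompson,84.20,8.72,4.14,18.36
Pachylemur insignis,EA,Thompson,77.00,7.79,3.71,16.38
Pachylemur insignis,EB,Thompson,84.90,8.81,4.18,18.56
Pachylemur insignis,EC,Thompson,79.50,8.11,3.86,17.06
Pachylemur insignis,ED,Thompson,78.60,8.00,3.80,16.82
Pachylemur insignis,EE,Thompson,71.90,7.15,3.40,15.00
Pachylemur insignis,EF,Thompson,75.00,7.54,3.59,15.84
Pachylemur insignis,EG,Thompson,79.70,8.14,3.87,17.12
Pachylemur insignis,EH,Thompson,75.60,7.61,3.62,16.00
Pachylemur insignis,EI,Thompson,87.90,9.21,4.37,19.40
Pachylemur insignis,EJ,Thompson,83.30,8.60,4.09,18.11
Pachylemur insignis,EK,Thompson,68.90,6.77,3.23,14.21
Pachylemur insignis,EL,Thompson,73.40,7.33,3.49,15.41
Pachylemur insignis,EM,Thompson,75.70,7.63,3.63,16.03
Pachylemur insignis,EN,Thompson,88.60,9.30,4.41,19.60
Pachylemur insignis,EO,Thompson,81.00,8.30,3.95,17.47
Pachylemur insignis,EP,Thompson,103.20,11.27,5.33,23.83
Pachylemur insignis,EQ,Thompson,80.00,8.18,3.89,17.20
Pachylemur insignis,ER,Thompson,70.20,6.93,3.30,14.55
Pachylemur insignis,ES,Thompson,85.10,8.84,4.20,18.61
Pachylemur insignis,ET,Thompson,83.40,8.62,4.09,18.14
Pachylemur insignis,PIn1,Jungers,83.69,8.65,4.11,18.22
Pachylemur insignis,PIn2,Jungers,72.38,7.21,3.43,15.13
Pachylemur insignis,PIn3,Jungers,90.78,9.59,4.55,20.22
Pachylemur insignis,PIn4,Jungers,110.18,12.24,5.78,25.92
Pachylemur insignis,PIn9,Jungers,80.20,8.20,3.90,17.25
Pachylemur insignis,PIn10,Jungers,89.06,9.36,4.44,19.73
Pachylemur insignis,PIn11,Jungers,71.16,7.05,3.36,14.81
Pachylemur insignis,PIn17,Jungers,55.30,5.13,2.46,10.73
Pachylemur insignis,PIn18,Jungers,63.60,6.12,2.92,12.83
Pachylemur jullyi,PJ1,Jungers,92.50,9.82,4.65,20.71
Pachylemur jullyi,PJ2,Jungers,83.83,8.67,4.12,18.26
Pachylemur jullyi,PJ7,Jungers,96.64,10.37,4.91,21.91
Pachylemur jullyi,PJ8,Jungers,94.99,10.15,4.81,21.43
Paleopropithecus ingens,PI2,Jungers,275.04,38.78,17.88,84.13
Paleopropithecus ingens,PI5,Jungers,156.99,19.13,8.96,40.84
Paleopropithecus ingens,PI7,Jungers,203.40,26.51,12.33,57.00
Paleopropithecus ingens,CB,Thompson,264.20,36.86,17.01,79.87
Paleopropithecus maximus,PM4,Jungers,230.22,30.99,14.36,66.87
Paleopropithecus maximus,PM5,Jungers,264.29,36.88,17.02,79.91
Paleopropithecus maximus,PM6,Jungers,251.77,34.69,16.03,75.05
Paleopropithecus maximus,CA,Thompson,214.30,28.31,13.15,60.97
Paleopropithecus maximus,CC,Thompson,228.90,30.77,14.26,66.38
Paleopropithecus maximus,CD,Thompson,163.80,20.18,9.44,43.13
Paleopropithecus maximus,CG,Thompson,215.50,28.51,13.24,61.41
Paleopropithecus maximus,CH,Thompson,236.00,31.97,14.81,69.04
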