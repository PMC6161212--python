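label,api,w_api,tg_C,density_powder_kg_m3,density_extrudate_kg_m3,cp25_J_per_gK,cp150_J_per_gK
COP,,0,107,1178,1191,1.013,1.720
CXB 10%,Celecoxib,0.10,104,1230,1208,1.142,1.819
CXB 30%,Celecoxib,0.30,101,1279,1237,1.011,1.878
LOR 10%,Loratadine,0.10,96,1215,1202,1.143,2.003
LOR 30%,Loratadine,0.30,75,1200,1204,1.097,1.864
NAP 10%,Naproxen,0.10,92,1190,1202,1.182,1.963
NAP 30%,Naproxen,0.30,71,1217,1209,1.117,1.883
PZQ 10%,Praziquantel,0.10,96,1220,1200,1.165,1.899
PZQ 30%,Praziquantel,0.30,72,1200,1209,1.104,1.862
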