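name,tg_C,delta_cp_J_per_gK,melting_point_C,molecular_weight,note
Celecoxib,56.8,0.39,160.9,381.4,
Loratadine,34.9,0.30,134.6,382.9,
Naproxen,6.7,0.23,156.1,230.3,Tg measured with 10% copovidone weight fraction (recrystallization tendency)
Praziquantel,35.9,0.37,138.3,312.4,
Copovidone,107,0.40,,,
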