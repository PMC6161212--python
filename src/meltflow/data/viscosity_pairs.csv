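label,tg_C,eta0_measured_Pa_s,eta0_estimated_Pa_s,temperature_C
CXB 10%,104,40791,56292,150
CXB 30%,101,9381,29114,150
LOR 30%,75,1488,343,150
NAP 10%,92,7198,7141,150
NAP 30%,71,259,165,150
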