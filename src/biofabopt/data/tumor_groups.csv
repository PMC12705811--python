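group,L_day0,S_day0,L_day20,S_day20,vol_day0,vol_day20
EAC,0.61,0.47,1.53,1.18,0.07,1.06
collagen,0.64,0.49,1.13,0.87,0.08,0.42
DOX,0.61,0.47,0.90,0.69,0.07,0.21
Sv-CollNPs,0.64,0.47,0.98,0.70,0.08,0.24
DOX/collagen,0.65,0.49,0.89,0.69,0.08,0.21
DOX/Sv-CollNPs,0.65,0.50,0.74,0.53,0.08,0.10
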