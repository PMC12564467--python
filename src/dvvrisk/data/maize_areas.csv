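country,mha_y1,mha_y2
Albania,0.05,0.05
Austria,0.58,0.62
Belarus,0.32,0.35
Belgium,0.06,0.05
Bosnia and Herz.,0.19,0.20
Bulgaria,0.55,0.58
Croatia,0.25,0.27
Czechia,0.08,0.09
Estonia,0.00,0.00
France,1.45,1.52
Germany,0.46,0.49
Greece,0.13,0.15
Hungary,0.95,1.03
Italy,1.05,1.15
Latvia,0.01,0.01
Lithuania,0.02,0.02
Luxembourg,0.00,0.01
Moldova,0.42,0.46
Netherlands,0.02,0.02
North Macedonia,0.12,0.12
Poland,0.75,0.85
Romania,2.50,2.50
Serbia,0.92,0.98
Slovakia,0.18,0.20
Slovenia,0.04,0.04
Spain,0.62,0.66
Switzerland,0.02,0.02
Turkey,0.85,0.95
Ukraine,3.90,4.10
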