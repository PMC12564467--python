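country,lon,lat,risk_2034,risk_2054,risk_2074
Albania,20.00,41.00,HR,HR,HR
Austria,14.55,47.52,MR,MR,HR
Belarus,27.70,53.70,LR,LR,MR
Belgium,4.47,50.85,LR,MR,MR
Bosnia and Herz.,17.67,44.00,HR,HR,HR
Bulgaria,25.00,43.00,HR,HR,HR
Croatia,16.00,45.10,MR,HR,HR
Czechia,15.47,49.82,MR,MR,MR
France,2.21,46.22,MR,HR,HR
Germany,10.45,51.16,LR,MR,MR
Greece,22.95,39.07,HR,HR,HR
Hungary,19.00,47.00,MR,MR,HR
Italy,12.50,42.83,HR,HR,HR
Luxembourg,6.13,49.75,MR,MR,MR
Moldova,28.85,47.00,MR,MR,HR
Netherlands,5.55,52.37,LR,LR,MR
North Macedonia,21.43,41.61,HR,HR,HR
Poland,19.15,52.12,LR,LR,MR
Romania,25.00,45.94,MR,HR,HR
Serbia,20.80,44.00,HR,HR,HR
Slovakia,19.70,48.70,MR,MR,HR
Slovenia,14.50,46.12,MR,HR,HR
Spain,-4.00,40.42,HR,HR,HR
Switzerland,8.23,46.80,MR,HR,HR
Turkey,35.00,39.00,HR,HR,HR
Ukraine,31.00,49.00,MR,MR,MR
Lithuania,24.00,55.20,LR,LR,LR
Latvia,25.00,57.00,LR,LR,LR
Estonia,25.00,58.60,LR,LR,LR
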