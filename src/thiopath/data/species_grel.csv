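id,name,formula,grel_kcal_mol,pathway,provenance,note
CO2,carbon dioxide,CO2,0.0,reference,definition,reference compound
H2,dihydrogen,H2,0.0,reference,definition,reference compound
H2O,water,H2O,0.0,reference,definition,reference compound
H2S,hydrogen sulfide,H2S,0.0,reference,definition,reference compound
CH3SH,methanethiol,CH4S,-19.2,shared,printed,
1a,glycolaldehyde,C2H4O2,-0.5,C2,printed,formose C2 linchpin
1b,mercaptoaldehyde,C2H4OS,-6.2,C2-thiol,printed,worked formation-reaction example
2a,glycolaldehyde hemithioacetal,C3H8O2S,-19.2,C2,printed,
7,glyoxal,C2H2O2,,glyoxal,unprinted,alpha-dicarbonyl start; absolute value not published
27,4-thiothreose cyclic hemithioacetal,C4H8O3S,-10.6,C4,printed,
CH2O,formaldehyde,CH2O,7.9,C4,printed,Cannizzaro coupling partner
32,S-linked thioester from 27 oxidation,C4H6O3S,-6.3,C4,printed,
CH3OH,methanol,CH4O,-11.2,C4,printed,Cannizzaro coupling product
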