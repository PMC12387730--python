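pathway,step_id,label,dG_kcal_mol,barrier_fwd_kcal_mol,ts_grel_kcal_mol,provenance,note
C2,add_a,1a + CH3SH -> 2a,0.5,19.4,-0.3,printed,eight-center TS with two explicit waters
C2,dehydration_a,2a -> 3 + H2O,-1.4,26.0,,printed,rate-determining step of the C2 pathway
C2,tautomerize_a,3 -> 4,-21.6,9.4,,printed,enol-to-keto gives the thioester
C2,hydrolysis_a,4 + H2O -> 6 + CH3SH,-6.1,,,printed,composite two-step hydrolysis via tetrahedral intermediate 5
C2-thiol,add_b,1b + CH3SH -> 2b,0.7,16.3,,printed,barrier ~3 kcal below the non-thiol analog
C2-thiol,eliminate_h2s_b,2b -> 3 + H2S,3.6,53.3,,printed,H2S elimination; prohibitively high barrier
glyoxal,add_8,7 + CH3SH -> 8,-7.1,10.4,,printed,activated alpha-dicarbonyl start
glyoxal,enolize_9,8 -> 9,7.9,28.0,,printed,rate-determining step of the glyoxal pathway
glyoxal,enolize_10,9 -> 10,-19.2,19.7,,printed,disproportionation-driven
glyoxal,hydrolysis_12,10 + H2O -> 12 + CH3SH,-4.7,,,printed,composite hydrolysis to glycolic acid
C3,add_14a,13a + CH3SH -> 14a,0.1,19.4,,printed,
C3,dehydrate_15a,13a -> 15a + H2O,-6.8,31.1,,printed,barrier also quoted later as 33.1 (see inconsistencies)
C3,add_16a,15a + CH3SH -> 16a,4.8,21.5,,printed,
C3,dehydrate_14a_16a,14a -> 16a + H2O,,55.4,,printed,dG unprinted; two-route closure requires -2.1
C3,tautomerize_17a,16a -> 17a,-13.5,15.5,-7.7,printed,
C3,tautomerize_18a,17a -> 18a,10.5,,-5.3,printed,barrier follows from printed TS grel
C3,tautomerize_19a,18a -> 19a,-16.5,16.4,,printed,thioester formed
C3,hydrolysis_21a,19a + H2O -> 21a + CH3SH,-4.5,,,printed,composite hydrolysis to lactic acid
C3-thiol,dehydrate_15b,13b -> 15b + H2O,-2.6,25.3,,printed,
C3-thiol,add_16b,15b + CH3SH -> 16b,6.8,17.7,,printed,
C3-thiol,add_14b,13b + CH3SH -> 14b,2.7,17.1,,printed,
C3-thiol,dehydrate_14b_16b,14b -> 16b + H2O,-1.5,29.2,,printed,two-route sums disagree by 3.0 (see inconsistencies)
C3-thiol,tautomerize_17b,16b -> 17b,-7.4,24.3,3.3,printed,
C3-thiol,tautomerize_18b,17b -> 18b,4.1,,3.8,printed,barrier follows from printed TS grel
C3-thiol,tautomerize_19b,18b -> 19b,-20.4,8.8,,printed,
C3-thiol,hydrolysis_21b,19b + H2O -> 21b + CH3SH,-5.9,,,printed,composite hydrolysis to thiolactic acid analog
C3-thiol,eliminate_h2s_22,14b -> 22 + H2S,0.8,36.6,,printed,
C3-thiol,tautomerize_23,22 -> 23,-18.9,10.8,,printed,
C3-thiol,hydrolysis_25,23 + H2O -> 25 + CH3SH,-6.4,,,printed,composite hydrolysis to 3-hydroxypropanoic acid
C3-thiol,add_14c,13c + CH3SH -> 14c,0.5,20.7,,printed,3-thioglyceraldehyde start
C3-thiol,eliminate_h2s_14c,14c -> 16a + H2S,,50.4,,printed,dG unprinted; prohibitively high barrier
C4,cyclize,26 -> 27,-1.5,14.1,,printed,intramolecular hemithioacetal formation
C4,dehydrate,27 -> 28 + H2O,-1.2,53.4,,printed,prohibitively high barrier
C4,tautomerize,28 -> 29,-20.4,6.1,,printed,
C4,hydrolysis,29 + H2O -> 31,-2.0,,,printed,composite hydrolysis to 2-deoxy-4-thiothreonic acid
C4-cannizzaro,cannizzaro,27 + CH2O -> 32 + CH3OH,-14.8,25.4,,printed,intermolecular disproportionation coupled to CH2O reduction
C4-cannizzaro,hydrolysis_34,32 + H2O -> 34,-4.8,,,printed,composite hydrolysis to 4-thiothreonic acid
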