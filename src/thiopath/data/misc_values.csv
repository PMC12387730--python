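key,value,units,provenance,note
atp_keq_prime,6.3e4,dimensionless,printed,ATP hydrolysis apparent equilibrium constant at pH 7 (eQuilibrator)
atp_dG_prime,-6.5,kcal/mol,printed,ATP hydrolysis transformed standard dG at 298.15 K
net_1a_to_4,-22.5,kcal/mol,printed,net sugar-to-thioester change for the C2 pathway
net_13a_to_19a,-21.4,kcal/mol,printed,net sugar-to-thioester change for the C3 pathway
enol_18a_vs_16a,-3.0,kcal/mol,printed,enol 18a more stable than 16a
stabilization_26_to_31,25.1,kcal/mol,printed,acid product more stable than 4-thiothreose
cannizzaro_coupled_dG,-14.8,kcal/mol,printed,27 + CH2O -> 32 + CH3OH from four printed grel values
barrier_13a_15a_first,31.1,kcal/mol,printed,13a -> 15a barrier at first mention
barrier_13a_15a_alt,33.1,kcal/mol,printed,13a -> 15a barrier as re-quoted later; stored unresolved
thioester_hydrolysis_exergonic_min,5.0,kcal/mol,printed,summary range of thioester hydrolysis exergonicity
thioester_hydrolysis_exergonic_max,7.0,kcal/mol,printed,summary range of thioester hydrolysis exergonicity
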