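pathway,label,species,total_kcal_mol,provenance,note
C2,start,1a;CH3SH,-19.7,printed,sum of the two printed member grel values
C2,final,6;CH3SH,-48.2,printed,combined final products including released CH3SH
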