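species,convention,carbon_numbers,provenance,note
1a,heteroatom,1;2,printed,glycolaldehyde backbone carbons
4,heteroatom,0;3,printed,thioester backbone carbons; intramolecular disproportionation vs 1a
4,standard,3,printed,carbonyl carbon under electronegativity partitioning
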