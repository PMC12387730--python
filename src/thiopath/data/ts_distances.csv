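ts,pathway,bond_class,role,distance_A,provenance,note
TS(1a-2a),C2,C-S,forming,2.37,printed,
TS(1a-2a),C2,S-H,breaking,1.74,printed,
TS(1a-2a),C2,O-H,transfer,1.05,printed,lower end of the printed 1.05-1.45 proton-transfer range
TS(1a-2a),C2,O-H,transfer,1.45,printed,upper end of the printed 1.05-1.45 proton-transfer range
TS(2a-3),C2,C-O,breaking,1.79,printed,
TS(2a-3),C2,C-H,breaking,1.47,printed,
TS(3-4),C2,C-H,forming,1.57,printed,a little long but reasonable
TS(4-5),C2,C-O,forming,1.64,printed,shorter than typical but reasonable
TS(5-6),C2,C-S,breaking,2.70,printed,noticeably longer than the expected window
TS(2b-3),C2-thiol,C-S,breaking,2.65,printed,slightly long
TS(13a-15a),C3,C-O,breaking,1.62,printed,
TS(13a-15a),C3,C-H,breaking,1.66,printed,C-H breaking runs ahead of C-O
TS(15a-16a),C3,C-S,forming,2.61,printed,longer than the C2 case but in range
TS(15a-16a),C3,S-H,breaking,1.87,printed,
TS(16a-17a),C3,C-H,forming,1.54,printed,
TS(17a-18a),C3,C-H,breaking,1.63,printed,
TS(26-27),C4,C-S,forming,2.23,printed,ring-closing contact
TS(26-27),C4,S-H,breaking,1.75,printed,
TS(30-31),C4,C-S,breaking,2.63,printed,no extra explicit waters needed
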