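# Methods

## Reference state and the G_rel ledger

All energies live on one axis: the relative Gibbs free energy `G_rel`,
defined per species as the ΔG of its formation reaction from CO₂, H₂, H₂O
and H₂S, each pinned at exactly 0.0 kcal/mol. The formation reaction is the
unique solution of the 4×4 element-balance system over {C, H, O, S}; it is
solved in exact rational arithmetic (Gaussian elimination over `Fraction`)
because G_rel correctness depends on the balance being exact, and floats
enter only when energies are evaluated. H₂O is reported on the product side
by convention; negative coefficients simply mean the compound sits on the
other side, and non-CHOS elements are rejected rather than guessed at.

Aqueous free energies are assembled from quantum-chemistry component
energies as

```
G_aq = 627.5095·(E_elec + ZPE + H_corr) − T·f·S_gas/1000 + G_solv
```

* `E_elec`, `ZPE`, `H_corr` in hartree (converted at 627.5095 kcal/mol);
* `S_gas` in cal/(mol·K), multiplied by `T/1000` to yield kcal/mol;
* `G_solv` in kcal/mol from an implicit-solvent model (an input, never
  computed here);
* `T = 298.15 K`, `f = 0.5` — the *half-entropy rule*: on dissolution a
  molecule retains roughly a constant half of its gas-phase entropy. The
  factor is applied to the **total** gas-phase entropy; whether it should
  exclude the vibrational part is genuinely ambiguous in the protocols this
  emulates, so the literal reading is used and the factor is configurable
  in `LedgerConfig` (0 ≤ f ≤ 1).

`G_rel` then follows as `G_aq(X) + ν_H₂O·G_aq(H₂O) − ν_CO₂·G_aq(CO₂) −
ν_H₂·G_aq(H₂) − ν_H₂S·G_aq(H₂S)`. Reference compounds come out at exactly 0
whatever their absolute `G_aq`; adding any consistent per-element offset to
all `E_elec` values cancels identically (tested). Energies are kept at full
precision internally; display rounds to 0.1 kcal/mol, matching the
precision at which such values are customarily printed. `K ↔ ΔG`
conversion uses `ΔG = −RT ln K` with `R = 1.987204×10⁻³ kcal/(mol·K)`.

## Networks, ladders, barriers

A pathway state is a **multiset** of species — spectators (unreacted
CH₃SH, released H₂O or H₂S) stay in every state so totals are comparable
along the whole curve. Steps carry optional transition-state nodes whose
`G_rel` sits on the same axis; explicit assisting water molecules used in
upstream TS optimizations are recorded (`n_assist`) but never added to
state totals, since published TS values are already relative quantities on
the ladder axis. Step ΔG is a pure difference of state totals (element
balance is verified when formulas are supplied); `ΔG‡(forward) −
ΔG‡(reverse) = ΔG` holds identically. A step without a TS node has *no*
barrier information — asking for its barrier raises rather than returning 0.

The rate-determining step of a ladder is the transition state with the
maximum `G_rel`; ties break to the earliest step and are reported as tied
(published data never tie; exact synthetic data can). Hess-cycle auditing
works at two levels: route pairs of (possibly rounded, independently
printed) step ΔG values, with a default 0.25 kcal/mol tolerance absorbing
0.1-kcal input rounding; and whole-network cycle bases (via networkx),
where a network evaluated from a single G_rel table must close every cycle
to 1e-9.

## The packaged published dataset

`thiopath/data/*.csv` stores, verbatim, the published values for the C₂
(glycolaldehyde/mercaptoaldehyde), glyoxal, C₃ (glyceraldehyde and its 2-
and 3-thio analogs) and C₄ (4-thiothreose, intramolecular and
Cannizzaro-coupled) pathways: species G_rel, step ΔG and forward barriers,
printed TS G_rel values and bond distances, carbon oxidation numbers, and
headline scalars. Every row carries a provenance tag; `printed` rows are
never modified by code. Ladders are reconstructed per branch from an
anchor plus printed increments. Anchors are printed where available (C₂
start −19.7; the 27+CH₂O state −2.7); the C₃ anchors are derived from a
printed absolute TS G_rel minus its printed barrier; the glyoxal branch has
no printed absolute value anywhere and is anchored at 0 relative to its own
start. Because printed values are rounded to 0.1 kcal/mol, chained totals
can differ from printed state totals by ~0.1 (the C₂ final state chains to
−48.3 against a printed −48.2); fixture comparisons therefore use a
0.15 kcal/mol tolerance, while exact synthetic data is held to 1e-9.

Two internal inconsistencies of the source are retained as data: the
13a→15a barrier appears in print as both 31.1 and 33.1 kcal/mol (both
stored, neither preferred), and the two printed routes 13b→16b disagree by
3.0 kcal/mol — a Hess violation the tooling flags but does not repair.

## Oxidation-state conventions

Two bookkeeping conventions are first-class because the published carbon
numbers are not all reproducible under one:

* **standard** — electronegativity partitioning on the Pauling scale
  (H 2.20, C 2.55, S 2.58, O 3.44); each bond's electrons go to the more
  electronegative partner, ties contribute 0, and a neutral molecule's
  numbers sum to zero. S sits just above C, so a C–S bond oxidizes carbon:
  the thioester carbonyl carbon (=O, –S, –C) lands at +3.
* **heteroatom** — bond-to-heteroatom counting: +1 per bond order to O or
  S, 0 for bonds to C or H. This reproduces the published glycolaldehyde
  backbone values {+1, +2} (the standard convention gives {−1, +1}).

Disproportionation detection compares sorted carbon multisets of
stoichiometrically matched sets (optionally restricted to backbone atoms,
excluding e.g. a thiol-derived methyl) and flags when one carbon rises
while another falls.

## Transition-state geometry

Plain single/multi-frame XYZ files are parsed with line-numbered error
reporting; watched breaking/forming contacts are classified by their
elongation ratio over reference covalent single bonds (C–S 1.82, C–O 1.43,
C–H 1.09, S–H 1.34, O–H 0.96 Å, all overridable) against a default
1.20–1.40 window. Proton-transfer contacts behave differently from
heavy-atom bond changes, so per-class window overrides are supported rather
than forcing one window on all contact types. Verdicts are monotone in
distance by construction.

## Synthetic generator

The quantum-chemistry layer is out of scope, so every pipeline stage is
tested against planted ground truth. Species tables sample formulas with
C ≤ 6, H ≤ 14, O ≤ 6, S ≤ 2 (the size range of the pathway chemistry) and a
planted G_rel uniform on [−60, +20] kcal/mol (the span the real ledger
occupies); ZPE (0.02–0.2 hartree), H_corr (0.002–0.008 hartree), S_gas
(40–120 cal/(mol·K)) and G_solv (−15–0 kcal/mol) are drawn from realistic
ranges and `E_elec` is back-solved so the formation-reaction ΔG equals the
planted value exactly — exercising the full G_aq formula rather than
trivial zeros. An optional rounding-noise mode rounds the back-solved
target to 0.1 kcal/mol, bounding recovery error at 0.05 and calibrating the
fixture tolerances. Networks chain states drawn from one table (so every
cycle closes exactly) with each TS placed above both adjacent minima; the
planted RDS is the per-branch argmax. All sampling uses an integer-seeded
`numpy.random.Generator`: one seed, identical bytes, any platform.

What the generator does **not** emulate: real DFT error structure (the
~2–3 kcal/mol systematic barrier error of carbonyl chemistry protocols),
conformer-selection noise, or correlated errors between related species.
Passing recovery tests therefore demonstrates the correctness of the
ledger/network arithmetic, not the accuracy of any quantum-chemistry
protocol.

## Problem sizes and numerical choices

Default test sizes — 100 seeds × 6 species for ledger recovery, 1000
random ladders for RDS brute-force agreement, 150–200 Hypothesis examples
per property — keep the full suite in a few seconds while covering the
combinatorics. Degenerate inputs fail loudly by policy: empty states sum
to 0, but empty pathways, ladders without transition states, missing
species, non-chaining steps, singular reference sets and malformed files
all raise named errors rather than returning defaults.

## Known limitations

No kinetics (no Eyring rates, no flux simulation), no pKa/protonation
modelling (acids are treated in their neutral COOH form), no 3D structure
perception beyond XYZ distance measurement, and no automated network
generation — networks are declared, not discovered.
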