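"""Physical constants and tabulated reference values.

All energies are reported in thermochemical kcal/mol unless a name says
otherwise; temperatures in kelvin; distances in angstrom.
"""

from __future__ import annotations

#: Hartree -> kcal/mol (CODATA hartree, thermochemical calorie).
HARTREE_TO_KCAL: float = 627.5095

#: Gas constant in kcal/(mol K).
R_KCAL: float = 1.987204e-3

#: Default temperature (K) for thermal corrections and K <-> dG conversion.
T_DEFAULT: float = 298.15

#: Fraction of gas-phase entropy retained in aqueous solution
#: (the "half entropy" rule for implicit-solvent free energies).
ENTROPY_FACTOR_DEFAULT: float = 0.5

#: Elements handled by the formula/oxidation machinery.
SUPPORTED_ELEMENTS: frozenset[str] = frozenset({"C", "H", "O", "S"})

#: Pauling electronegativities. Note S (2.58) > C (2.55): a C-S bond
#: oxidizes carbon, which is what puts a thioester carbonyl carbon at +3.
PAULING_EN: dict[str, float] = {"H": 2.20, "C": 2.55, "O": 3.44, "S": 2.58}

#: Typical single-bond covalent lengths (angstrom) used as references for
#: transition-state elongation ratios. Overridable in BondReferenceConfig.
COVALENT_SINGLE_BOND_A: dict[str, float] = {
    "C-S": 1.82,
    "C-O": 1.43,
    "C-H": 1.09,
    "S-H": 1.34,
    "O-H": 0.96,
}

#: Default elongation window for breaking/forming bonds at a transition
#: state: 20-40 % longer than the covalent single bond.
ELONGATION_WINDOW_DEFAULT: tuple[float, float] = (1.20, 1.40)
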