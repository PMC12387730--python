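"""Oxidation-state assignment on molecular graphs and disproportionation checks.

Sugar -> thioester conversion is driven by an internal redox event: one
carbon climbs to the thioester/acid level while a neighbour drops. Detecting
it only needs formal oxidation numbers on a 2D bond graph.

Two conventions are implemented, because literature values for these
pathways are printed under different bookkeeping:

``standard``
    Electronegativity partitioning (Pauling scale): each bonding electron
    pair goes to the more electronegative partner; ties contribute 0. The
    per-atom numbers of a neutral molecule sum to zero. With S (2.58)
    marginally above C (2.55), a C-S bond oxidizes the carbon, putting a
    thioester carbonyl carbon at +3.

``heteroatom``
    Bond-to-heteroatom counting: each bond to O or S contributes +1 per bond
    order; bonds to H or C contribute 0. This reproduces printed sugar
    carbon numbers such as glycolaldehyde {+1, +2}, which the standard
    convention does not (it gives {-1, +1}).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .constants import PAULING_EN, SUPPORTED_ELEMENTS

__all__ = [
    "MolecularGraph",
    "OxidationAssignment",
    "DisproportionationReport",
    "GraphError",
    "ConventionError",
    "oxidation_states",
    "redox_delta",
    "CONVENTIONS",
]

CONVENTIONS = ("standard", "heteroatom")


class GraphError(ValueError):
    """Invalid molecular graph."""


class ConventionError(ValueError):
    """Unknown or mismatched oxidation-number convention."""


@dataclass(frozen=True)
class MolecularGraph:
    """Minimal 2D molecule: atoms with formal charges, bonds with integer order.

    No aromaticity, stereochemistry or 3D perception — just what oxidation
    bookkeeping needs.
    """

    atoms: tuple[tuple[str, int], ...]
    bonds: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "atoms", tuple((el, int(q)) for el, q in self.atoms)
        )
        object.__setattr__(
            self, "bonds", tuple((int(i), int(j), int(o)) for i, j, o in self.bonds)
        )
        n = len(self.atoms)
        if n == 0:
            raise GraphError("graph has no atoms")
        for el, _ in self.atoms:
            if el not in SUPPORTED_ELEMENTS:
                raise GraphError(f"unsupported element {el!r}")
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise GraphError(f"bad bond indices ({i}, {j}) for {n} atoms")
            if order < 1:
                raise GraphError(f"bond order must be >= 1, got {order}")

    @property
    def net_charge(self) -> int:
        return sum(q for _, q in self.atoms)

    @classmethod
    def from_atom_bond_text(cls, text: str) -> "MolecularGraph":
        """Parse a minimal text block::

            atoms: C C O S
            bonds: 0-1 1=2 1-3

        ``-`` is a single bond, ``=`` double, ``#`` triple. Charges may be
        appended to an atom symbol as ``O-`` / ``O+``.
        """
        atoms: list[tuple[str, int]] = []
        bonds: list[tuple[int, int, int]] = []
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(":")
            key = key.strip().lower()
            if key == "atoms":
                for tok in rest.split():
                    charge = 0
                    while tok and tok[-1] in "+-":
                        charge += 1 if tok[-1] == "+" else -1
                        tok = tok[:-1]
                    atoms.append((tok, charge))
            elif key == "bonds":
                order_map = {"-": 1, "=": 2, "#": 3}
                for tok in rest.split():
                    for sym, order in order_map.items():
                        if sym in tok:
                            i, _, j = tok.partition(sym)
                            bonds.append((int(i), int(j), order))
                            break
                    else:
                        raise GraphError(f"cannot parse bond token {tok!r}")
            else:
                raise GraphError(f"unknown line {line!r}")
        return cls(tuple(atoms), tuple(bonds))

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        """Build from SMILES via RDKit (optional dependency), hydrogens explicit."""
        try:
            from rdkit import Chem
        except ImportError as exc:  # pragma: no cover
            raise ImportError("from_smiles requires rdkit") from exc
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise GraphError(f"RDKit could not parse SMILES {smiles!r}")
        mol = Chem.AddHs(mol)
        atoms = tuple(
            (a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()
        )
        bonds = tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
            for b in mol.GetBonds()
        )
        return cls(atoms, bonds)


@dataclass(frozen=True)
class OxidationAssignment:
    """Per-atom oxidation numbers under one stated convention."""

    graph: MolecularGraph
    numbers: tuple[int, ...]
    convention: str

    def carbon_numbers(self, atom_indices: Iterable[int] | None = None) -> list[int]:
        """Sorted oxidation numbers of (a subset of) the carbon atoms."""
        if atom_indices is None:
            idx = [i for i, (el, _) in enumerate(self.graph.atoms) if el == "C"]
        else:
            idx = list(atom_indices)
            for i in idx:
                if self.graph.atoms[i][0] != "C":
                    raise GraphError(f"atom {i} is not carbon")
        return sorted(self.numbers[i] for i in idx)


def oxidation_states(mol: MolecularGraph, convention: str = "standard") -> OxidationAssignment:
    """Assign formal oxidation numbers to every atom of `mol`.

    See the module docstring for the two conventions.
    """
    if convention not in CONVENTIONS:
        raise ConventionError(
            f"unknown convention {convention!r}; expected one of {CONVENTIONS}"
        )
    numbers = [q for _, q in mol.atoms] if convention == "standard" else [0] * len(mol.atoms)
    for i, j, order in mol.bonds:
        el_i, el_j = mol.atoms[i][0], mol.atoms[j][0]
        if convention == "standard":
            en_i, en_j = PAULING_EN[el_i], PAULING_EN[el_j]
            if en_i > en_j:
                numbers[i] -= order
                numbers[j] += order
            elif en_j > en_i:
                numbers[i] += order
                numbers[j] -= order
        else:  # heteroatom bond counting
            if el_j in ("O", "S"):
                numbers[i] += order
            if el_i in ("O", "S"):
                numbers[j] += order
    return OxidationAssignment(mol, tuple(numbers), convention)


@dataclass(frozen=True)
class DisproportionationReport:
    """Comparison of matched carbon oxidation-number multisets."""

    before: tuple[int, ...]
    after: tuple[int, ...]
    delta: tuple[int, ...]
    disproportionation: bool
    spread_before: int
    spread_after: int


def redox_delta(
    before: OxidationAssignment,
    after: OxidationAssignment,
    atoms_before: Sequence[int] | None = None,
    atoms_after: Sequence[int] | None = None,
) -> DisproportionationReport:
    """Compare carbon oxidation numbers of two stoichiometrically matched sets.

    The carbon multisets (optionally restricted to the given atom indices —
    e.g. the sugar backbone, excluding a thiol-derived methyl) are sorted and
    compared position-wise. The disproportionation flag is set when one
    carbon's number rises while another's falls.
    """
    if before.convention != after.convention:
        raise ConventionError(
            f"convention mismatch: {before.convention!r} vs {after.convention!r}"
        )
    a = before.carbon_numbers(atoms_before)
    b = after.carbon_numbers(atoms_after)
    if len(a) != len(b):
        raise GraphError(
            f"carbon sets are not matched: {len(a)} vs {len(b)} atoms"
        )
    delta = tuple(y - x for x, y in zip(a, b))
    rose = any(d > 0 for d in delta)
    fell = any(d < 0 for d in delta)
    return DisproportionationReport(
        before=tuple(a),
        after=tuple(b),
        delta=delta,
        disproportionation=rose and fell,
        spread_before=(max(a) - min(a)) if a else 0,
        spread_after=(max(b) - min(b)) if b else 0,
    )
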