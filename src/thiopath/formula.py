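"""Molecular formulas and formation-reaction balancing over CHOS.

Every species in the ledger is written as the unique element-balanced
"formation reaction" from the four reference compounds

    nu_CO2 CO2 + nu_H2 H2 + nu_H2S H2S  ->  species + nu_H2O H2O

The coefficients are the solution of a 4x4 linear system (one equation per
element C, H, O, S) and are kept as exact rationals: G_rel correctness
downstream depends on the balance being exact, so no floating point enters
until energies are evaluated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .constants import SUPPORTED_ELEMENTS

__all__ = [
    "ElementCounts",
    "FormationReaction",
    "FormulaError",
    "UnsupportedElementError",
    "UnbalanceableSpeciesError",
    "parse_formula",
    "balance_formation",
    "DEFAULT_REFERENCES",
]


class FormulaError(ValueError):
    """Malformed formula string."""


class UnsupportedElementError(FormulaError):
    """Formula contains an element outside the supported CHOS set."""


class UnbalanceableSpeciesError(ValueError):
    """No unique formation reaction exists for the given reference set."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCounts:
    """Element composition of one species, e.g. {C: 2, H: 4, O: 1, S: 1}."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = set(self.counts) - SUPPORTED_ELEMENTS
        if bad:
            raise UnsupportedElementError(
                f"unsupported element(s) {sorted(bad)}; supported: C, H, O, S"
            )
        if any(v < 0 for v in self.counts.values()):
            raise FormulaError("negative element count")
        if not any(v > 0 for v in self.counts.values()):
            raise FormulaError("empty composition")
        # normalized form: zero entries dropped
        object.__setattr__(
            self, "counts", {k: int(v) for k, v in self.counts.items() if v}
        )

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self):
        return iter(self.counts)

    def to_formula(self) -> str:
        """Hill-like formula string (C, H, then O, S alphabetically)."""
        order = ["C", "H", "O", "S"]
        parts = []
        for el in order:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-like formula string over {C, H, O, S}.

    >>> parse_formula("C2H4OS").counts
    {'C': 2, 'H': 4, 'O': 1, 'S': 1}
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"unsupported element {element!r} in formula {text!r}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return ElementCounts(counts)


#: Reference compounds, in reporting order. H2O is the conventional
#: product-side reference; the other three sit on the reactant side.
DEFAULT_REFERENCES: tuple[ElementCounts, ...] = (
    parse_formula("CO2"),
    parse_formula("H2"),
    parse_formula("H2O"),
    parse_formula("H2S"),
)

_ELEMENT_ORDER = ("C", "H", "O", "S")


@dataclass(frozen=True)
class FormationReaction:
    """Stoichiometry of the formation reaction of `target` from the references.

    ``nu_co2``, ``nu_h2``, ``nu_h2s`` are reactant-side coefficients and
    ``nu_h2o`` is the product-side coefficient; any of them may be negative,
    meaning that compound sits on the opposite side.
    """

    target: ElementCounts
    nu_co2: Fraction
    nu_h2: Fraction
    nu_h2o: Fraction
    nu_h2s: Fraction

    def element_totals(self) -> ElementCounts:
        """Reconstruct the target composition from the coefficients (exact)."""
        refs = dict(zip(("CO2", "H2", "H2O", "H2S"), DEFAULT_REFERENCES))
        totals = {el: Fraction(0) for el in _ELEMENT_ORDER}
        for name, nu in (
            ("CO2", self.nu_co2),
            ("H2", self.nu_h2),
            ("H2S", self.nu_h2s),
        ):
            for el in _ELEMENT_ORDER:
                totals[el] += nu * refs[name][el]
        for el in _ELEMENT_ORDER:
            totals[el] -= self.nu_h2o * refs["H2O"][el]
        clean = {}
        for el, v in totals.items():
            if v:
                if v.denominator != 1 or v < 0:
                    raise UnbalanceableSpeciesError(
                        f"non-integral reconstructed count {v} for {el}"
                    )
                clean[el] = int(v)
        return ElementCounts(clean)

    def __str__(self) -> str:
        def fmt(nu: Fraction) -> str:
            return str(nu) if nu.denominator != 1 else str(nu.numerator)

        lhs = [
            f"{fmt(nu)} {name}"
            for nu, name in (
                (self.nu_co2, "CO2"),
                (self.nu_h2, "H2"),
                (self.nu_h2s, "H2S"),
            )
            if nu != 0
        ]
        rhs = [f"1 {self.target.to_formula()}"]
        if self.nu_h2o != 0:
            rhs.append(f"{fmt(self.nu_h2o)} H2O")
        return " + ".join(lhs or ["0"]) + " -> " + " + ".join(rhs)


def _solve_exact(
    columns: Sequence[Sequence[Fraction]], rhs: Sequence[Fraction]
) -> list[Fraction]:
    """Solve the square system (columns as basis vectors) by exact elimination."""
    n = len(rhs)
    # augmented matrix rows: equations over elements
    aug = [[columns[j][i] for j in range(n)] + [rhs[i]] for i in range(n)]
    for col in range(n):
        pivot = next((r for r in range(col, n) if aug[r][col] != 0), None)
        if pivot is None:
            raise UnbalanceableSpeciesError(
                "singular element-balance system: reference set does not "
                "span the target's element space"
            )
        aug[col], aug[pivot] = aug[pivot], aug[col]
        inv = Fraction(1) / aug[col][col]
        aug[col] = [x * inv for x in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0:
                factor = aug[r][col]
                aug[r] = [a - factor * b for a, b in zip(aug[r], aug[col])]
    return [aug[i][n] for i in range(n)]


def balance_formation(
    target: ElementCounts | str,
    references: Sequence[ElementCounts] = DEFAULT_REFERENCES,
) -> FormationReaction:
    """Balance the formation reaction of `target` against the reference set.

    The default references CO2 / H2 / H2O / H2S span CHOS space with a unique
    solution for every CHOS formula. Coefficients are exact rationals.

    >>> str(balance_formation("C2H4OS"))
    '2 CO2 + 4 H2 + 1 H2S -> 1 C2H4OS + 3 H2O'
    """
    if isinstance(target, str):
        target = parse_formula(target)
    if len(references) != len(_ELEMENT_ORDER):
        raise UnbalanceableSpeciesError(
            f"need exactly {len(_ELEMENT_ORDER)} reference compounds, "
            f"got {len(references)}"
        )
    columns = [
        [Fraction(ref[el]) for el in _ELEMENT_ORDER] for ref in references
    ]
    rhs = [Fraction(target[el]) for el in _ELEMENT_ORDER]
    coeffs = _solve_exact(columns, rhs)
    by_formula = {
        ref.to_formula(): c for ref, c in zip(references, coeffs)
    }
    try:
        rxn = FormationReaction(
            target=target,
            nu_co2=by_formula["CO2"],
            nu_h2=by_formula["H2"],
            nu_h2o=-by_formula["H2O"],  # product side is positive
            nu_h2s=by_formula["H2S"],
        )
    except KeyError as exc:  # custom reference sets keep positional meaning
        raise UnbalanceableSpeciesError(
            f"reference set must contain {exc} (or use the default set)"
        ) from exc
    # Exactness check: reconstruct and compare.
    if rxn.element_totals().counts != target.counts:
        raise UnbalanceableSpeciesError(
            f"balance verification failed for {target.to_formula()}"
        )
    return rxn
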