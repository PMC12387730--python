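"""Aqueous free energies and the relative free-energy (G_rel) ledger.

Quantum-chemistry post-processing hands us, per species, the component
energies of a standard implicit-solvent protocol: electronic energy, zero
point energy and thermal enthalpy correction (hartree), gas-phase entropy
(cal/(mol K)) and a solvation free energy (kcal/mol). The aqueous free
energy is assembled as

    G_aq = 627.5095 * (E_elec + ZPE + H_corr)  -  T * f * S_gas / 1000  +  G_solv

with f the entropy retention factor: in water a molecule keeps only a
roughly constant fraction (~0.5) of its gas-phase entropy, so the default
is f = 0.5 at T = 298.15 K.

Absolute G_aq values are huge and basis-set dependent; what is comparable
across species is the relative free energy

    G_rel(X) = dG of the formation reaction of X from CO2 / H2 / H2O / H2S

with every reference compound pinned at exactly 0.0 kcal/mol. G_rel plays
the role of a free energy of formation on this four-compound reference
state, and step dG / barrier arithmetic downstream is pure differences of
G_rel values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from . import constants
from .formula import (
    DEFAULT_REFERENCES,
    ElementCounts,
    FormationReaction,
    balance_formation,
    parse_formula,
)

__all__ = [
    "ComponentEnergies",
    "LedgerConfig",
    "SpeciesRecord",
    "Ledger",
    "LedgerError",
    "hartree_to_kcal",
    "aqueous_free_energy",
    "grel",
    "dG_from_keq",
    "keq_from_dG",
    "TABLE_COLUMNS",
]

#: Input table schema (delimited text): one row per species.
TABLE_COLUMNS = (
    "id",
    "formula",
    "E_elec_hartree",
    "ZPE_hartree",
    "Hcorr_hartree",
    "Sgas_cal_mol_K",
    "Gsolv_kcal_mol",
)


class LedgerError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentEnergies:
    """Per-species component energies in their native units."""

    E_elec: float  # hartree
    ZPE: float  # hartree, >= 0
    H_corr: float  # hartree
    S_gas: float  # cal/(mol K), > 0
    G_solv: float  # kcal/mol

    def __post_init__(self) -> None:
        for name in ("E_elec", "ZPE", "H_corr", "S_gas", "G_solv"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise LedgerError(f"missing or non-finite component {name!r}")
        if self.ZPE < 0:
            raise LedgerError("ZPE must be >= 0")
        if self.S_gas <= 0:
            raise LedgerError("gas-phase entropy must be positive")


@dataclass(frozen=True)
class LedgerConfig:
    """Protocol constants for assembling G_aq and G_rel."""

    temperature: float = constants.T_DEFAULT
    entropy_factor: float = constants.ENTROPY_FACTOR_DEFAULT
    hartree_to_kcal: float = constants.HARTREE_TO_KCAL
    references: tuple[ElementCounts, ...] = DEFAULT_REFERENCES

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise LedgerError("temperature must be positive")
        if not 0.0 <= self.entropy_factor <= 1.0:
            raise LedgerError("entropy retention factor must be in [0, 1]")


@dataclass(frozen=True)
class SpeciesRecord:
    """One ledger row: identity, components and the derived energies."""

    identifier: str
    composition: ElementCounts
    components: ComponentEnergies
    G_aq: float  # kcal/mol
    G_rel: float  # kcal/mol
    formation: FormationReaction


def hartree_to_kcal(x: float, constant: float = constants.HARTREE_TO_KCAL) -> float:
    """Convert hartree to kcal/mol (1 hartree = 627.5095 kcal/mol)."""
    if not math.isfinite(x):
        raise LedgerError("non-finite energy")
    return x * constant


def aqueous_free_energy(c: ComponentEnergies, cfg: LedgerConfig | None = None) -> float:
    """Assemble the aqueous free energy (kcal/mol) from component energies.

    The entropy term converts S_gas from cal to kcal (/1000) and retains
    only ``cfg.entropy_factor`` of it.
    """
    cfg = cfg or LedgerConfig()
    enthalpic = hartree_to_kcal(
        c.E_elec + c.ZPE + c.H_corr, cfg.hartree_to_kcal
    )
    entropic = cfg.temperature * cfg.entropy_factor * c.S_gas / 1000.0
    return enthalpic - entropic + c.G_solv


def grel(
    species_G_aq: float,
    composition: ElementCounts | str,
    reference_G_aq: Mapping[str, float],
    cfg: LedgerConfig | None = None,
) -> tuple[float, FormationReaction]:
    """Relative free energy of a species: dG of its formation reaction.

    ``reference_G_aq`` maps reference formulas ("CO2", "H2", "H2O", "H2S")
    to their aqueous free energies. Returns (G_rel, formation reaction).
    By construction every reference compound comes out at exactly 0.
    """
    cfg = cfg or LedgerConfig()
    if isinstance(composition, str):
        composition = parse_formula(composition)
    rxn = balance_formation(composition, cfg.references)
    missing = {"CO2", "H2", "H2O", "H2S"} - set(reference_G_aq)
    if missing:
        raise LedgerError(f"missing reference free energies for {sorted(missing)}")
    value = (
        species_G_aq
        + float(rxn.nu_h2o) * reference_G_aq["H2O"]
        - float(rxn.nu_co2) * reference_G_aq["CO2"]
        - float(rxn.nu_h2) * reference_G_aq["H2"]
        - float(rxn.nu_h2s) * reference_G_aq["H2S"]
    )
    return value, rxn


def dG_from_keq(K: float, T: float = constants.T_DEFAULT) -> float:
    """dG = -RT ln K in kcal/mol (R = 1.987204e-3 kcal/(mol K))."""
    if K <= 0:
        raise LedgerError("equilibrium constant must be positive")
    if T <= 0:
        raise LedgerError("temperature must be positive")
    return -constants.R_KCAL * T * math.log(K)


def keq_from_dG(dG: float, T: float = constants.T_DEFAULT) -> float:
    """Inverse of :func:`dG_from_keq`; exact round trip."""
    if T <= 0:
        raise LedgerError("temperature must be positive")
    return math.exp(-dG / (constants.R_KCAL * T))


class Ledger:
    """A table of species with derived G_aq and G_rel values.

    The reference compounds must be present in the input table (identified
    by formula); their G_rel is exactly 0 whatever their absolute G_aq.
    """

    def __init__(
        self,
        records: Mapping[str, tuple[ElementCounts, ComponentEnergies]],
        config: LedgerConfig | None = None,
    ) -> None:
        self.config = config or LedgerConfig()
        ref_formulas = {r.to_formula() for r in self.config.references}
        ref_G_aq: dict[str, float] = {}
        g_aq: dict[str, float] = {}
        for ident, (comp, energies) in records.items():
            g_aq[ident] = aqueous_free_energy(energies, self.config)
            f = comp.to_formula()
            if f in ref_formulas:
                # first row bearing a reference formula defines that reference
                ref_G_aq.setdefault(f, g_aq[ident])
        missing = ref_formulas - set(ref_G_aq)
        if missing:
            raise LedgerError(
                f"reference compound(s) {sorted(missing)} absent from the table"
            )
        self.species: dict[str, SpeciesRecord] = {}
        for ident, (comp, energies) in records.items():
            value, rxn = grel(g_aq[ident], comp, ref_G_aq, self.config)
            self.species[ident] = SpeciesRecord(
                identifier=ident,
                composition=comp,
                components=energies,
                G_aq=g_aq[ident],
                G_rel=value,
                formation=rxn,
            )

    def __getitem__(self, ident: str) -> SpeciesRecord:
        return self.species[ident]

    def __len__(self) -> int:
        return len(self.species)

    def __contains__(self, ident: str) -> bool:
        return ident in self.species

    def grel_table(self) -> dict[str, float]:
        """Mapping species id -> G_rel (kcal/mol), the network-layer currency."""
        return {k: v.G_rel for k, v in self.species.items()}

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: LedgerConfig | None = None) -> "Ledger":
        missing = set(TABLE_COLUMNS) - set(frame.columns)
        if missing:
            raise LedgerError(f"species table missing column(s) {sorted(missing)}")
        records: dict[str, tuple[ElementCounts, ComponentEnergies]] = {}
        for _, row in frame.iterrows():
            ident = str(row["id"])
            if ident in records:
                raise LedgerError(f"duplicate species id {ident!r}")
            comp = parse_formula(str(row["formula"]))
            energies = ComponentEnergies(
                E_elec=float(row["E_elec_hartree"]),
                ZPE=float(row["ZPE_hartree"]),
                H_corr=float(row["Hcorr_hartree"]),
                S_gas=float(row["Sgas_cal_mol_K"]),
                G_solv=float(row["Gsolv_kcal_mol"]),
            )
            records[ident] = (comp, energies)
        return cls(records, config)

    @classmethod
    def from_csv(cls, path, config: LedgerConfig | None = None, sep: str = ",") -> "Ledger":
        return cls.from_frame(pd.read_csv(path, sep=sep), config)

    def to_frame(self) -> pd.DataFrame:
        """Input columns plus derived G_aq and G_rel (full precision)."""
        rows = []
        for rec in self.species.values():
            c = rec.components
            rows.append(
                {
                    "id": rec.identifier,
                    "formula": rec.composition.to_formula(),
                    "E_elec_hartree": c.E_elec,
                    "ZPE_hartree": c.ZPE,
                    "Hcorr_hartree": c.H_corr,
                    "Sgas_cal_mol_K": c.S_gas,
                    "Gsolv_kcal_mol": c.G_solv,
                    "G_aq_kcal_mol": rec.G_aq,
                    "G_rel_kcal_mol": rec.G_rel,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)
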