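"""Synthetic species tables, networks and XYZ frames with planted ground truth.

The quantum-chemistry layer that produces real component-energy tables is
out of scope here, so every pipeline stage is exercised against generated
stand-ins instead: a species table whose component energies are back-solved
from a *planted* G_rel value (the ledger must recover it to numerical
precision), branching networks with a planted rate-determining step, and
toy XYZ frames for the geometry reader. All sampling uses an integer-seeded
``numpy.random.Generator``, so one seed gives byte-identical outputs on any
platform.

The back-solving construction: fix component energies for the four
reference compounds once, evaluate their G_aq, then for each species draw
ZPE / H_corr / S_gas / G_solv from realistic ranges and solve E_elec such
that the formation-reaction dG equals the planted G_rel exactly. This
exercises the full aqueous free-energy formula rather than trivial zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .formula import parse_formula
from .ledger import (
    ComponentEnergies,
    Ledger,
    LedgerConfig,
    aqueous_free_energy,
    grel,
)
from .network import ElementaryStep, ThermoState, TransitionStateNode

__all__ = ["SyntheticSpec", "gen_species_table", "gen_network", "gen_xyz_frames"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic generator (defaults are the study conditions)."""

    seed: int = 0
    n_species: int = 20
    max_counts: tuple[int, int, int, int] = (6, 14, 6, 2)  # C, H, O, S
    grel_range: tuple[float, float] = (-60.0, 20.0)  # kcal/mol
    zpe_range: tuple[float, float] = (0.02, 0.2)  # hartree
    hcorr_range: tuple[float, float] = (0.002, 0.008)  # hartree
    sgas_range: tuple[float, float] = (40.0, 120.0)  # cal/(mol K)
    gsolv_range: tuple[float, float] = (-15.0, 0.0)  # kcal/mol
    rounding_noise: bool = False  # round emitted energies to 0.1 kcal/mol

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise ValueError("n_species must be >= 0")


#: Fixed, arbitrary but realistic reference component energies; shared by
#: every synthetic table so that G_rel values are comparable across tables.
_REFERENCE_COMPONENTS: dict[str, ComponentEnergies] = {
    "CO2": ComponentEnergies(-188.58, 0.0117, 0.0025, 51.1, -0.4),
    "H2": ComponentEnergies(-1.17, 0.0100, 0.0023, 31.2, 1.0),
    "H2O": ComponentEnergies(-76.42, 0.0211, 0.0038, 45.1, -6.3),
    "H2S": ComponentEnergies(-399.35, 0.0152, 0.0033, 49.2, -0.5),
}


def _sample_formula(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    maxC, maxH, maxO, maxS = spec.max_counts
    while True:
        c = int(rng.integers(0, maxC + 1))
        h = int(rng.integers(0, maxH + 1))
        o = int(rng.integers(0, maxO + 1))
        s = int(rng.integers(0, maxS + 1))
        if c + h + o + s == 0:
            continue
        parts = []
        for el, n in (("C", c), ("H", h), ("O", o), ("S", s)):
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def gen_species_table(
    spec: SyntheticSpec, config: LedgerConfig | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate a component-energy table with planted G_rel ground truth.

    Returns (table, truth) where `table` has the ledger input schema (the
    four reference compounds included) and `truth` maps each synthetic
    species id to its planted G_rel. Without rounding noise the ledger
    recovers every planted value to numerical precision; with it, to the
    0.05 kcal/mol half-step of the 0.1-kcal rounding.
    """
    config = config or LedgerConfig()
    rng = np.random.default_rng(spec.seed)
    ref_G_aq = {
        f: aqueous_free_energy(c, config) for f, c in _REFERENCE_COMPONENTS.items()
    }
    rows = []
    for f, c in _REFERENCE_COMPONENTS.items():
        rows.append(
            {
                "id": f,
                "formula": f,
                "E_elec_hartree": c.E_elec,
                "ZPE_hartree": c.ZPE,
                "Hcorr_hartree": c.H_corr,
                "Sgas_cal_mol_K": c.S_gas,
                "Gsolv_kcal_mol": c.G_solv,
            }
        )
    truth: dict[str, float] = {}
    for k in range(spec.n_species):
        formula = _sample_formula(rng, spec)
        planted = float(rng.uniform(*spec.grel_range))
        zpe = float(rng.uniform(*spec.zpe_range))
        hcorr = float(rng.uniform(*spec.hcorr_range))
        sgas = float(rng.uniform(*spec.sgas_range))
        gsolv = float(rng.uniform(*spec.gsolv_range))
        # target aqueous free energy from the planted formation dG
        zero, rxn = grel(0.0, formula, ref_G_aq, config)
        g_aq_target = planted - zero
        if spec.rounding_noise:
            g_aq_target = round(g_aq_target, 1)
        e_elec = (
            (g_aq_target - gsolv + config.temperature * config.entropy_factor * sgas / 1000.0)
            / config.hartree_to_kcal
            - zpe
            - hcorr
        )
        ident = f"syn{k:03d}"
        truth[ident] = planted
        rows.append(
            {
                "id": ident,
                "formula": formula,
                "E_elec_hartree": e_elec,
                "ZPE_hartree": zpe,
                "Hcorr_hartree": hcorr,
                "Sgas_cal_mol_K": sgas,
                "Gsolv_kcal_mol": gsolv,
            }
        )
    return pd.DataFrame(rows, columns=list(rows[0].keys())), truth


@dataclass(frozen=True)
class SyntheticNetwork:
    """A generated branching network plus its planted answers."""

    branches: dict[str, list[ElementaryStep]]
    table: dict[str, float]
    planted_rds: dict[str, int]  # branch -> step index of the argmax TS


def gen_network(
    seed: int = 0,
    n_steps: int = 8,
    n_branches: int = 1,
    grel_range: tuple[float, float] = (-60.0, 20.0),
    barrier_range: tuple[float, float] = (5.0, 40.0),
    species: dict[str, float] | None = None,
) -> SyntheticNetwork:
    """Generate chaining branched pathways with a planted RDS per branch.

    All branches share a start state; every state's energy comes from one
    G_rel table, so each cycle of the resulting network closes exactly
    (state-function construction). Each step's TS is placed above both
    adjacent minima; the planted RDS is the argmax TS of each branch.

    When a ``species`` mapping (id -> G_rel, e.g. the planted truth of
    :func:`gen_species_table`) is given, states are drawn from those ids so
    the network and a species table form one coherent bundle; otherwise
    anonymous node ids with freshly sampled energies are used.
    """
    if n_steps < 1:
        raise ValueError("need at least one step per branch")
    if n_branches < 1:
        raise ValueError("need at least one branch")
    rng = np.random.default_rng(seed)
    pool = sorted(species) if species is not None else None
    if pool is not None and len(pool) < 2:
        raise ValueError("need at least two species to draw states from")
    table: dict[str, float] = {}

    def draw_node(default_name: str, avoid: str | None) -> str:
        if pool is None:
            table[default_name] = float(rng.uniform(*grel_range))
            return default_name
        choices = [p for p in pool if p != avoid]
        node = str(rng.choice(choices))
        table[node] = float(species[node])
        return node

    start = draw_node("start", None)
    branches: dict[str, list[ElementaryStep]] = {}
    planted: dict[str, int] = {}
    for b in range(n_branches):
        label = f"branch{b}"
        prev = start
        steps: list[ElementaryStep] = []
        ts_values: list[float] = []
        for k in range(n_steps):
            node = draw_node(f"{label}_s{k}", prev)
            lo = max(table[prev], table[node])
            ts_grel = lo + float(rng.uniform(*barrier_range))
            ts_values.append(ts_grel)
            steps.append(
                ElementaryStep(
                    ThermoState.of(prev),
                    ThermoState.of(node),
                    TransitionStateNode(f"TS({label}:{k})", ts_grel),
                    label=f"{label}:{k}",
                )
            )
            prev = node
        branches[label] = steps
        planted[label] = int(np.argmax(ts_values))
    return SyntheticNetwork(branches, table, planted)


def gen_xyz_frames(
    seed: int = 0, n_frames: int = 1, n_atoms: int = 20, box: float = 6.0
):
    """Random toy XYZ frames (uniform CHOS atoms in a cube) for I/O tests."""
    from .geometry import XYZStructure

    rng = np.random.default_rng(seed)
    elements = np.array(["C", "H", "O", "S"])
    frames = []
    for k in range(n_frames):
        symbols = tuple(rng.choice(elements, size=n_atoms))
        coords = rng.uniform(-box / 2, box / 2, size=(n_atoms, 3))
        frames.append(XYZStructure(f"synthetic frame {k}", symbols, coords))
    return frames
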