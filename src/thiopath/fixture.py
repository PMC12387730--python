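"""Curated published G_rel dataset for the C2-C4 sugar-to-thioester pathways.

The packaged CSVs under ``thiopath/data`` hold, verbatim, the published
values of the computational study these pathways come from: per-species
G_rel values, per-step dG and forward barriers, transition-state G_rel
values and bond distances, carbon oxidation numbers and a few headline
scalars (ATP-hydrolysis comparison, net pathway changes). Rows carry a
``provenance`` column: ``printed`` values are never modified by code;
quantities the source implies but does not print (e.g. the absolute anchor
of a ladder reconstructed from a printed TS G_rel and its barrier) are
computed here at load time and labelled *derived*.

Two internal inconsistencies of the source are retained as data, not
corrected: the 13a -> 15a barrier is printed both as 31.1 and 33.1, and the
two printed routes 13b -> 16b disagree by 3.0 kcal (a Hess-cycle violation,
presumably a typo in one printed value).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .network import ElementaryStep, EnergyLadder, ThermoState, TransitionStateNode

__all__ = ["ReferencePathways", "reference_pathways"]

#: Ladder anchors: (branch, start label, start total, list of step_ids).
#: Anchors marked "derived" are reconstructed from printed values at load
#: time; the glyoxal branch has no printed absolute value anywhere, so its
#: ladder is relative to its own start (anchor 0.0).
_BRANCHES: tuple[tuple[str, str, str, tuple[str, ...]], ...] = (
    ("C2", "1a + CH3SH", "printed",
     ("add_a", "dehydration_a", "tautomerize_a", "hydrolysis_a")),
    ("C2-thiol", "1b + CH3SH", "derived",
     ("add_b", "eliminate_h2s_b")),
    ("glyoxal", "7 + CH3SH", "relative",
     ("add_8", "enolize_9", "enolize_10", "hydrolysis_12")),
    ("C3", "13a + CH3SH", "derived",
     ("dehydrate_15a", "add_16a", "tautomerize_17a", "tautomerize_18a",
      "tautomerize_19a", "hydrolysis_21a")),
    ("C3-thiol", "13b + CH3SH", "derived",
     ("dehydrate_15b", "add_16b", "tautomerize_17b", "tautomerize_18b",
      "tautomerize_19b", "hydrolysis_21b")),
    ("C3-thiol-h2s", "13b + CH3SH", "derived",
     ("add_14b", "eliminate_h2s_22", "tautomerize_23", "hydrolysis_25")),
    ("C4", "26", "derived",
     ("cyclize", "dehydrate", "tautomerize", "hydrolysis")),
    ("C4-cannizzaro", "27 + CH2O", "printed",
     ("cannizzaro", "hydrolysis_34")),
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("thiopath.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class ReferencePathways:
    """Read-only view over the packaged published-value tables."""

    species: pd.DataFrame
    steps: pd.DataFrame
    state_totals: pd.DataFrame
    ts_distances: pd.DataFrame
    oxidation: pd.DataFrame
    misc: pd.DataFrame

    # ------------------------------------------------------------- lookups

    def species_grel(self) -> dict[str, float]:
        """Printed species G_rel values (kcal/mol); unprinted species omitted."""
        sub = self.species.dropna(subset=["grel_kcal_mol"])
        return dict(zip(sub["id"], sub["grel_kcal_mol"].astype(float)))

    def formulas(self) -> dict[str, str]:
        return dict(zip(self.species["id"], self.species["formula"]))

    def step(self, pathway: str, step_id: str) -> pd.Series:
        sub = self.steps[
            (self.steps["pathway"] == pathway) & (self.steps["step_id"] == step_id)
        ]
        if sub.empty:
            raise KeyError(f"no step {step_id!r} in pathway {pathway!r}")
        return sub.iloc[0]

    def step_dG(self, pathway: str, step_id: str) -> float:
        v = self.step(pathway, step_id)["dG_kcal_mol"]
        if pd.isna(v):
            raise KeyError(f"dG of {pathway}/{step_id} was not published")
        return float(v)

    def step_barrier(self, pathway: str, step_id: str) -> float:
        v = self.step(pathway, step_id)["barrier_fwd_kcal_mol"]
        if pd.isna(v):
            raise KeyError(f"barrier of {pathway}/{step_id} was not published")
        return float(v)

    def state_total(self, pathway: str, label: str) -> float:
        sub = self.state_totals[
            (self.state_totals["pathway"] == pathway)
            & (self.state_totals["label"] == label)
        ]
        if sub.empty:
            raise KeyError(f"no state total {label!r} for pathway {pathway!r}")
        return float(sub.iloc[0]["total_kcal_mol"])

    def value(self, key: str) -> float:
        sub = self.misc[self.misc["key"] == key]
        if sub.empty:
            raise KeyError(f"no scalar value {key!r}")
        return float(sub.iloc[0]["value"])

    def carbon_numbers(self, species: str, convention: str) -> list[int]:
        sub = self.oxidation[
            (self.oxidation["species"] == species)
            & (self.oxidation["convention"] == convention)
        ]
        if sub.empty:
            raise KeyError(f"no oxidation numbers for {species!r}/{convention!r}")
        return sorted(int(x) for x in str(sub.iloc[0]["carbon_numbers"]).split(";"))

    def known_inconsistencies(self) -> list[dict]:
        """The source's internal inconsistencies, reported not repaired."""
        return [
            {
                "what": "13a -> 15a forward barrier printed twice",
                "values": (self.value("barrier_13a_15a_first"),
                           self.value("barrier_13a_15a_alt")),
                "resolution": "both stored; neither preferred",
            },
            {
                "what": "two printed routes 13b -> 16b disagree (Hess violation)",
                "route_via_15b": [self.step_dG("C3-thiol", "dehydrate_15b"),
                                  self.step_dG("C3-thiol", "add_16b")],
                "route_via_14b": [self.step_dG("C3-thiol", "add_14b"),
                                  self.step_dG("C3-thiol", "dehydrate_14b_16b")],
                "residual_kcal_mol": 3.0,
                "resolution": "flagged by hess tooling; no correction applied",
            },
        ]

    # ------------------------------------------------------------- ladders

    def _anchor(self, branch: str) -> float:
        g = self.species_grel()
        if branch == "C2":
            return self.state_total("C2", "start")
        if branch == "C2-thiol":
            return g["1b"] + g["CH3SH"]
        if branch == "glyoxal":
            return 0.0  # no absolute value published anywhere on this branch
        if branch == "C3":
            # state {16a, H2O(+CH3SH spectators)} pinned by printed TS grel -7.7
            # minus printed barrier 15.5; walk back the two preceding steps.
            state_16a = (
                float(self.step("C3", "tautomerize_17a")["ts_grel_kcal_mol"])
                - self.step_barrier("C3", "tautomerize_17a")
            )
            return state_16a - (
                self.step_dG("C3", "dehydrate_15a") + self.step_dG("C3", "add_16a")
            )
        if branch in ("C3-thiol", "C3-thiol-h2s"):
            state_16b = (
                float(self.step("C3-thiol", "tautomerize_17b")["ts_grel_kcal_mol"])
                - self.step_barrier("C3-thiol", "tautomerize_17b")
            )
            return state_16b - (
                self.step_dG("C3-thiol", "dehydrate_15b")
                + self.step_dG("C3-thiol", "add_16b")
            )
        if branch == "C4":
            return g["27"] - self.step_dG("C4", "cyclize")
        if branch == "C4-cannizzaro":
            return g["27"] + g["CH2O"]
        raise KeyError(f"unknown branch {branch!r}")

    def ladder(self, branch: str) -> EnergyLadder:
        """Reconstruct one branch's energy ladder from printed increments.

        TS points use the printed forward barrier where published, falling
        back to a printed absolute TS G_rel; steps with neither get no TS
        point.
        """
        spec = next((b for b in _BRANCHES if b[0] == branch), None)
        if spec is None:
            raise KeyError(f"unknown branch {branch!r}")
        _, start_label, _, step_ids = spec
        pathway = "C3-thiol" if branch == "C3-thiol-h2s" else branch
        increments = []
        current = self._anchor(branch)
        for sid in step_ids:
            row = self.step(pathway, sid)
            dG = float(row["dG_kcal_mol"])
            if pd.notna(row["barrier_fwd_kcal_mol"]):
                fwd = float(row["barrier_fwd_kcal_mol"])
            elif pd.notna(row["ts_grel_kcal_mol"]):
                fwd = float(row["ts_grel_kcal_mol"]) - current
            else:
                fwd = None
            increments.append((str(row["label"]), dG, fwd))
            current += dG
        return EnergyLadder.from_increments(
            start_label, self._anchor(branch), increments, branch=branch
        )

    def ladders(self) -> dict[str, EnergyLadder]:
        return {b[0]: self.ladder(b[0]) for b in _BRANCHES}

    # --------------------------------------------------------- C2 network

    def c2_table(self) -> tuple[dict[str, float], dict[str, str]]:
        """G_rel table and formulas for the full C2 step network.

        Printed values are used where published (1a, CH3SH, 2a, references);
        the remaining species (enol 3, thioester 4, acetic acid 6) are
        reconstructed from printed step increments at load time.
        """
        g = self.species_grel()
        table = {k: g[k] for k in ("1a", "CH3SH", "2a", "H2O", "H2S", "CO2", "H2")}
        table["3"] = table["2a"] + self.step_dG("C2", "dehydration_a")  # H2O at 0
        table["4"] = table["3"] + self.step_dG("C2", "tautomerize_a")
        table["6"] = (
            table["4"] + self.step_dG("C2", "hydrolysis_a") - table["CH3SH"]
        )
        formulas = {
            "1a": "C2H4O2", "CH3SH": "CH4S", "2a": "C3H8O2S", "3": "C3H6OS",
            "4": "C3H6OS", "6": "C2H4O2", "H2O": "H2O", "H2S": "H2S",
            "CO2": "CO2", "H2": "H2",
        }
        return table, formulas

    def c2_steps(self) -> list[ElementaryStep]:
        """The C2 pathway as element-balanced elementary steps with TS nodes.

        TS G_rel values: the addition TS is printed (-0.3); the dehydration
        and tautomerization TSs are reconstructed as state + printed barrier.
        """
        table, _ = self.c2_table()
        ts_add = float(self.step("C2", "add_a")["ts_grel_kcal_mol"])
        ts_dehyd = table["2a"] + self.step_barrier("C2", "dehydration_a")
        ts_taut = (table["3"] + table["H2O"]) + self.step_barrier("C2", "tautomerize_a")
        return [
            ElementaryStep(
                ThermoState.of("1a", "CH3SH"), ThermoState.of("2a"),
                TransitionStateNode("TS(1a-2a)", ts_add, n_assist=2),
                label="add_a",
            ),
            ElementaryStep(
                ThermoState.of("2a"), ThermoState.of("3", "H2O"),
                TransitionStateNode("TS(2a-3)", ts_dehyd, n_assist=1),
                label="dehydration_a",
            ),
            ElementaryStep(
                ThermoState.of("3", "H2O"), ThermoState.of("4", "H2O"),
                TransitionStateNode("TS(3-4)", ts_taut),
                label="tautomerize_a",
            ),
            ElementaryStep(
                ThermoState.of("4", "H2O"), ThermoState.of("6", "CH3SH"),
                None,
                label="hydrolysis_a",
            ),
        ]


@lru_cache(maxsize=1)
def reference_pathways() -> ReferencePathways:
    """Load the packaged published-value dataset (cached)."""
    return ReferencePathways(
        species=_load("species_grel.csv"),
        steps=_load("steps.csv"),
        state_totals=_load("state_totals.csv"),
        ts_distances=_load("ts_distances.csv"),
        oxidation=_load("oxidation_numbers.csv"),
        misc=_load("misc_values.csv"),
    )
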