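"""Reaction networks, energy ladders, barriers and rate-determining steps.

A pathway is a chain of thermodynamic *states* — multisets of species,
spectators included, so that totals are comparable along the whole curve
(an unconsumed thiol or a released water stays in the state) — connected by
elementary steps, each optionally carrying a transition-state node with its
own G_rel. Everything is difference arithmetic on one G_rel axis:

    dG(step)        = G_rel(products) - G_rel(reactants)
    dG'(forward)    = G_rel(TS) - G_rel(reactant state)
    dG'(reverse)    = G_rel(TS) - G_rel(product state)

so forward - reverse barrier = step dG, pathway sums telescope, and any two
routes between the same endpoints must agree (Hess's law) up to the
rounding of their inputs. The rate-determining step of a ladder is the step
whose transition state sits highest on the G_rel axis.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .formula import ElementCounts, parse_formula

__all__ = [
    "ThermoState",
    "TransitionStateNode",
    "ElementaryStep",
    "EnergyLadder",
    "LadderPoint",
    "RateDeterminingStep",
    "HessResult",
    "NetworkError",
    "UnknownSpeciesError",
    "state_energy",
    "reaction_dG",
    "barrier",
    "net_pathway_dG",
    "build_ladder",
    "find_rds",
    "hess_residual",
    "hess_solve_unknown",
    "hess_check_network",
    "export_diagram",
    "load_network",
    "dump_network",
    "compare_branches",
]


class NetworkError(ValueError):
    pass


class UnknownSpeciesError(NetworkError):
    pass


GrelTable = Mapping[str, float]


@dataclass(frozen=True)
class ThermoState:
    """A multiset of species whose G_rel values sum to one curve point."""

    species: tuple[tuple[str, int], ...]
    label: str = ""

    @classmethod
    def of(cls, *species: str, label: str = "", **counted: int) -> "ThermoState":
        """``ThermoState.of("1a", "CH3SH")`` or ``ThermoState.of(H2O=2)``."""
        c: Counter[str] = Counter(species)
        c.update(counted)
        return cls(tuple(sorted(c.items())), label or "+".join(sorted(c.elements())))

    def multiset(self) -> Counter:
        return Counter(dict(self.species))

    def energy(self, table: GrelTable) -> float:
        return state_energy(self, table)

    def element_totals(self, formulas: Mapping[str, str | ElementCounts]) -> Counter:
        totals: Counter = Counter()
        for sp, n in self.species:
            if sp not in formulas:
                raise UnknownSpeciesError(f"no formula for species {sp!r}")
            comp = formulas[sp]
            if isinstance(comp, str):
                comp = parse_formula(comp)
            for el in comp:
                totals[el] += n * comp[el]
        return totals

    def __str__(self) -> str:
        return self.label or "+".join(
            f"{n} {sp}" if n > 1 else sp for sp, n in self.species
        )


@dataclass(frozen=True)
class TransitionStateNode:
    """A transition state placed on the same G_rel axis as the minima.

    ``n_assist`` counts explicit water/catalyst molecules included in the
    upstream TS optimization; they are bookkeeping only and are never added
    to state totals.
    """

    identifier: str
    G_rel: float
    n_assist: int = 0
    xyz_ref: str | None = None

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.G_rel):
            raise NetworkError(f"non-finite TS G_rel for {self.identifier!r}")


@dataclass(frozen=True)
class ElementaryStep:
    reactants: ThermoState
    products: ThermoState
    ts: TransitionStateNode | None = None
    label: str = ""

    @property
    def name(self) -> str:
        return self.label or f"{self.reactants} -> {self.products}"

    def reversed(self) -> "ElementaryStep":
        return ElementaryStep(
            self.products, self.reactants, self.ts, label=f"rev({self.name})"
        )


def state_energy(state: ThermoState, table: GrelTable) -> float:
    """Exact sum of member G_rel values, multiplicities respected."""
    total = 0.0
    for sp, n in state.species:
        if sp not in table:
            raise UnknownSpeciesError(f"species {sp!r} not in the G_rel table")
        total += n * table[sp]
    return total


def _check_balance(step: ElementaryStep, formulas: Mapping[str, str | ElementCounts]) -> None:
    lhs = step.reactants.element_totals(formulas)
    rhs = step.products.element_totals(formulas)
    if lhs != rhs:
        raise NetworkError(
            f"element imbalance in step {step.name!r}: {dict(lhs)} vs {dict(rhs)}"
        )


def reaction_dG(
    step: ElementaryStep,
    table: GrelTable,
    formulas: Mapping[str, str | ElementCounts] | None = None,
) -> float:
    """dG = products total - reactants total; antisymmetric under reversal.

    If a formula mapping is given, element balance between the two states is
    verified first.
    """
    if formulas is not None:
        _check_balance(step, formulas)
    return state_energy(step.products, table) - state_energy(step.reactants, table)


def barrier(step: ElementaryStep, table: GrelTable, direction: str = "forward") -> float:
    """dG' of a step: TS G_rel minus the chosen side's state total.

    A step without a declared transition state has *no* barrier information
    (it is not barrierless); asking for one is an error.
    """
    if step.ts is None:
        raise NetworkError(
            f"step {step.name!r} has no transition-state node: "
            "no barrier information available"
        )
    if direction not in ("forward", "reverse"):
        raise NetworkError(f"direction must be forward|reverse, got {direction!r}")
    side = step.reactants if direction == "forward" else step.products
    return step.ts.G_rel - state_energy(side, table)


def _check_chaining(pathway: Sequence[ElementaryStep]) -> None:
    for k, (a, b) in enumerate(itertools.pairwise(pathway)):
        if a.products.multiset() != b.reactants.multiset():
            raise NetworkError(
                f"pathway breaks between step {k} ({a.name!r}) and step "
                f"{k + 1} ({b.name!r}): product state {a.products} != "
                f"reactant state {b.reactants}"
            )


def net_pathway_dG(pathway: Sequence[ElementaryStep], table: GrelTable) -> float:
    """Sum of step dG along a chaining pathway (telescopes to the endpoints)."""
    if not pathway:
        raise NetworkError("empty pathway")
    _check_chaining(pathway)
    return sum(reaction_dG(s, table) for s in pathway)


# ------------------------------------------------------------------ ladders


@dataclass(frozen=True)
class LadderPoint:
    kind: str  # "state" | "ts"
    label: str
    G_rel: float
    step_index: int | None = None  # for TS points: which step they belong to


@dataclass
class EnergyLadder:
    """Alternating minima / transition-state sequence on one G_rel axis."""

    points: list[LadderPoint] = field(default_factory=list)
    branch: str = ""

    @property
    def states(self) -> list[LadderPoint]:
        return [p for p in self.points if p.kind == "state"]

    @property
    def transition_states(self) -> list[LadderPoint]:
        return [p for p in self.points if p.kind == "ts"]

    def net_dG(self) -> float:
        s = self.states
        if not s:
            raise NetworkError("ladder has no state points")
        return s[-1].G_rel - s[0].G_rel

    def step_dGs(self) -> list[float]:
        s = self.states
        return [b.G_rel - a.G_rel for a, b in itertools.pairwise(s)]

    @classmethod
    def from_increments(
        cls,
        start_label: str,
        start_G_rel: float,
        steps: Iterable[tuple[str, float, float | None]],
        branch: str = "",
    ) -> "EnergyLadder":
        """Build a ladder from a start anchor and per-step (label, dG, dG'fwd).

        The third element of each step tuple is the forward barrier, or None
        for a step with no transition-state information.
        """
        points = [LadderPoint("state", start_label, start_G_rel)]
        current = start_G_rel
        for k, (label, dG, fwd_barrier) in enumerate(steps):
            if fwd_barrier is not None:
                points.append(
                    LadderPoint("ts", f"TS({label})", current + fwd_barrier, k)
                )
            current += dG
            points.append(LadderPoint("state", label.split("->")[-1].strip() or label, current))
        return cls(points, branch)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch": self.branch,
                "position": range(len(self.points)),
                "kind": [p.kind for p in self.points],
                "label": [p.label for p in self.points],
                "G_rel_kcal_mol": [p.G_rel for p in self.points],
            }
        )


def build_ladder(
    pathway: Sequence[ElementaryStep],
    table: GrelTable,
    branch: str = "",
) -> EnergyLadder:
    """Evaluate a chaining pathway into plottable ladder coordinates."""
    if not pathway:
        raise NetworkError("empty pathway")
    _check_chaining(pathway)
    first = pathway[0].reactants
    points = [LadderPoint("state", str(first), state_energy(first, table))]
    for k, step in enumerate(pathway):
        if step.ts is not None:
            points.append(LadderPoint("ts", step.ts.identifier, step.ts.G_rel, k))
        points.append(
            LadderPoint("state", str(step.products), state_energy(step.products, table))
        )
    return EnergyLadder(points, branch)


@dataclass(frozen=True)
class RateDeterminingStep:
    step_index: int
    ts_label: str
    ts_G_rel: float
    forward_barrier: float
    tied: bool


def find_rds(ladder: EnergyLadder) -> RateDeterminingStep:
    """Rate-determining step: the transition state highest on the G_rel axis.

    Ties are broken toward the earliest step and reported as tied. The
    forward barrier is measured from the state point immediately preceding
    the winning TS.
    """
    ts_points = ladder.transition_states
    if not ts_points:
        raise NetworkError("ladder has no transition states: no RDS defined")
    best = max(ts_points, key=lambda p: p.G_rel)  # max() keeps the earliest
    tied = sum(1 for p in ts_points if p.G_rel == best.G_rel) > 1
    idx = ladder.points.index(best)
    preceding = next(
        p for p in reversed(ladder.points[:idx]) if p.kind == "state"
    )
    return RateDeterminingStep(
        step_index=best.step_index if best.step_index is not None else -1,
        ts_label=best.label,
        ts_G_rel=best.G_rel,
        forward_barrier=best.G_rel - preceding.G_rel,
        tied=tied,
    )


# --------------------------------------------------------------- Hess checks


@dataclass(frozen=True)
class HessResult:
    route_a: float
    route_b: float
    residual: float
    flagged: bool
    tolerance: float


def hess_residual(
    dGs_a: Sequence[float],
    dGs_b: Sequence[float],
    tolerance: float = 0.25,
) -> HessResult:
    """Compare two routes between the same endpoints by their summed step dG.

    The default tolerance (0.25 kcal/mol) absorbs the 0.1-kcal rounding of
    published inputs; exact synthetic data should use a tight tolerance.
    """
    a, b = float(sum(dGs_a)), float(sum(dGs_b))
    residual = a - b
    return HessResult(a, b, residual, abs(residual) > tolerance, tolerance)


def hess_solve_unknown(
    dGs_a: Sequence[float], dGs_b: Sequence[float | None]
) -> float:
    """Value the single unknown (None) entry of route b must take for closure."""
    unknowns = [i for i, v in enumerate(dGs_b) if v is None]
    if len(unknowns) != 1:
        raise NetworkError(f"expected exactly one unknown, got {len(unknowns)}")
    known = sum(v for v in dGs_b if v is not None)
    return float(sum(dGs_a)) - float(known)


def hess_check_network(
    steps: Sequence[ElementaryStep],
    table: GrelTable | None = None,
    declared_dG: Mapping[str, float] | None = None,
    tolerance: float = 1e-9,
) -> list[tuple[list[str], float, bool]]:
    """Residuals around every independent cycle of a step network.

    States are graph nodes (keyed by multiset), steps are edges carrying a
    dG — evaluated from `table`, or taken from `declared_dG` (step label ->
    value) when given, which is how independently rounded published
    increments are audited. Each cycle of a cycle basis is walked with
    orientation signs: +dG along a step's direction, -dG against it. A
    network evaluated from a single G_rel table closes every cycle exactly;
    residuals above `tolerance` are flagged.
    """
    if table is None and declared_dG is None:
        raise NetworkError("need a G_rel table or declared step dG values")

    def step_dG(step: ElementaryStep) -> float:
        if declared_dG is not None:
            if step.name not in declared_dG:
                raise NetworkError(f"no declared dG for step {step.name!r}")
            return float(declared_dG[step.name])
        return reaction_dG(step, table)

    key = lambda st: tuple(sorted(st.multiset().items()))
    g = nx.Graph()
    for step in steps:
        u, v = key(step.reactants), key(step.products)
        if g.has_edge(u, v):
            continue  # parallel routes between the same pair keep the first edge
        g.add_edge(u, v, dG=step_dG(step), label=step.name, tail=u)
    out = []
    for cycle in nx.cycle_basis(g):
        total = 0.0
        labels = []
        ring = list(cycle) + [cycle[0]]
        for u, v in itertools.pairwise(ring):
            data = g.edges[u, v]
            sign = 1.0 if data["tail"] == u else -1.0
            total += sign * data["dG"]
            labels.append(data["label"])
        out.append((labels, total, abs(total) > tolerance))
    return out


# ------------------------------------------------------------------- export


def export_diagram(
    ladders: Sequence[EnergyLadder],
    csv_path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Superimpose one or more ladders into a tidy coordinate table.

    Returns a DataFrame of (branch, position, kind, label, G_rel_kcal_mol),
    deterministically ordered; optionally writes it as CSV and renders a
    simple stepped energy-diagram plot (one trace per branch).
    """
    if not ladders:
        raise NetworkError("no ladders to export")
    frame = pd.concat([l.to_frame() for l in ladders], ignore_index=True)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 5))
        for ladder in ladders:
            xs = range(len(ladder.points))
            ys = [p.G_rel for p in ladder.points]
            ax.plot(xs, ys, marker="o", label=ladder.branch or "pathway")
        ax.set_xlabel("reaction coordinate (ladder position)")
        ax.set_ylabel(r"$G_\mathrm{rel}$ (kcal/mol)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return frame


def ladder_from_frame(frame: pd.DataFrame, branch: str) -> EnergyLadder:
    """Inverse of :meth:`EnergyLadder.to_frame` for one branch."""
    sub = frame[frame["branch"] == branch].sort_values("position")
    if sub.empty:
        raise NetworkError(f"branch {branch!r} not present in the table")
    points = [
        LadderPoint(str(r["kind"]), str(r["label"]), float(r["G_rel_kcal_mol"]))
        for _, r in sub.iterrows()
    ]
    return EnergyLadder(points, branch)


# ------------------------------------------------------- structured-text I/O


def load_network(source) -> dict[str, list[ElementaryStep]]:
    """Read a YAML/JSON network definition into per-branch step lists.

    Schema::

        branches:
          - label: main
            steps:
              - label: "1a+CH3SH -> 2a"
                reactants: {"1a": 1, "CH3SH": 1}
                products: {"2a": 1}
                ts: {id: "TS(1a-2a)", grel: -0.3, n_assist: 2}
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "branches" not in data:
        raise NetworkError("network definition must contain a 'branches' list")
    branches: dict[str, list[ElementaryStep]] = {}
    for branch in data["branches"]:
        label = str(branch.get("label", f"branch{len(branches)}"))
        steps = []
        for k, s in enumerate(branch.get("steps", [])):
            try:
                reactants = ThermoState.of(**{str(a): int(n) for a, n in s["reactants"].items()})
                products = ThermoState.of(**{str(a): int(n) for a, n in s["products"].items()})
            except KeyError as exc:
                raise NetworkError(
                    f"branch {label!r} step {k}: missing {exc}"
                ) from exc
            ts = None
            if "ts" in s and s["ts"] is not None:
                ts_block = s["ts"]
                ts = TransitionStateNode(
                    identifier=str(ts_block.get("id", f"TS({label}:{k})")),
                    G_rel=float(ts_block["grel"]),
                    n_assist=int(ts_block.get("n_assist", 0)),
                    xyz_ref=ts_block.get("xyz"),
                )
            steps.append(
                ElementaryStep(reactants, products, ts, label=str(s.get("label", f"step{k}")))
            )
        if not steps:
            raise NetworkError(f"branch {label!r} has no steps")
        branches[label] = steps
    if not branches:
        raise NetworkError("network has no branches")
    return branches


def dump_network(branches: Mapping[str, Sequence[ElementaryStep]], stream=None) -> str:
    """Serialize per-branch step lists back to the YAML schema."""
    doc = {"branches": []}
    for label, steps in branches.items():
        entry = {"label": label, "steps": []}
        for s in steps:
            block = {
                "label": s.label,
                "reactants": dict(s.reactants.species),
                "products": dict(s.products.species),
            }
            if s.ts is not None:
                block["ts"] = {
                    "id": s.ts.identifier,
                    "grel": s.ts.G_rel,
                    "n_assist": s.ts.n_assist,
                }
                if s.ts.xyz_ref:
                    block["ts"]["xyz"] = s.ts.xyz_ref
            entry["steps"].append(block)
        doc["branches"].append(entry)
    text = yaml.safe_dump(doc, sort_keys=False)
    if stream is not None:
        stream.write(text)
    return text


# ------------------------------------------------------- branch comparison


def compare_branches(
    ladders: Sequence[EnergyLadder],
) -> pd.DataFrame:
    """Thermodynamic (net dG) and kinetic (highest TS) preference per branch.

    Mirrors the usual "kinetically preferred" discussion: the branch whose
    highest transition state is lowest wins kinetically; the branch with the
    most negative net dG wins thermodynamically.
    """
    rows = []
    for ladder in ladders:
        ts = ladder.transition_states
        rows.append(
            {
                "branch": ladder.branch,
                "net_dG_kcal_mol": ladder.net_dG(),
                "max_ts_G_rel_kcal_mol": max(p.G_rel for p in ts) if ts else float("nan"),
            }
        )
    frame = pd.DataFrame(rows)
    if frame["max_ts_G_rel_kcal_mol"].notna().any():
        kin = frame["max_ts_G_rel_kcal_mol"].idxmin()
        frame["kinetically_preferred"] = [i == kin for i in frame.index]
    thermo = frame["net_dG_kcal_mol"].idxmin()
    frame["thermodynamically_preferred"] = [i == thermo for i in frame.index]
    return frame
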