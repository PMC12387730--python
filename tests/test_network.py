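"""Energy ladders, barriers, rate-determining steps and Hess closure."""

import io

import numpy as np
import pytest

from thiopath.network import (
    ElementaryStep,
    EnergyLadder,
    NetworkError,
    ThermoState,
    TransitionStateNode,
    UnknownSpeciesError,
    barrier,
    build_ladder,
    compare_branches,
    dump_network,
    export_diagram,
    find_rds,
    hess_check_network,
    hess_residual,
    hess_solve_unknown,
    load_network,
    net_pathway_dG,
    reaction_dG,
    state_energy,
)
from thiopath.network import ladder_from_frame
from thiopath.synthetic import gen_network


# ------------------------------------------------------------ state energy


def test_state_energy_published_sums(c2):
    """The C2 start state {glycolaldehyde + CH3SH} sums to -19.7 kcal/mol
    and the combined final products land within printed rounding of -48.2."""
    steps, table, _ = c2
    assert state_energy(ThermoState.of("1a", "CH3SH"), table) == pytest.approx(-19.7)
    final = state_energy(ThermoState.of("6", "CH3SH"), table)
    assert final == pytest.approx(-48.2, abs=0.15)


def test_state_energy_multiplicity_and_unknown():
    table = {"A": -2.0, "B": 1.5}
    assert state_energy(ThermoState.of(A=2, B=1), table) == pytest.approx(-2.5)
    assert state_energy(ThermoState(()), table) == 0.0
    with pytest.raises(UnknownSpeciesError):
        state_energy(ThermoState.of("C"), table)


# -------------------------------------------------------------- step dG


def test_reaction_dG_thiol_addition(c2):
    """CH3SH + 1a -> 2a is marginally endergonic: -19.2 - (-19.7) = +0.5."""
    steps, table, formulas = c2
    assert reaction_dG(steps[0], table, formulas) == pytest.approx(0.5, abs=1e-9)


def test_reaction_dG_cannizzaro_coupled(ref):
    """27 + CH2O -> 32 + CH3OH from the four printed G_rel values: -14.8."""
    g = ref.species_grel()
    step = ElementaryStep(
        ThermoState.of("27", "CH2O"), ThermoState.of("32", "CH3OH")
    )
    assert reaction_dG(step, g) == pytest.approx(-14.8, abs=1e-9)


def test_reaction_dG_antisymmetric_and_null(c2):
    steps, table, formulas = c2
    fwd = reaction_dG(steps[1], table, formulas)
    rev = reaction_dG(steps[1].reversed(), table, formulas)
    assert fwd == -rev
    null = ElementaryStep(ThermoState.of("1a"), ThermoState.of("1a"))
    assert reaction_dG(null, table) == 0.0


def test_reaction_dG_rejects_element_imbalance():
    step = ElementaryStep(ThermoState.of("A"), ThermoState.of("B"))
    with pytest.raises(NetworkError):
        reaction_dG(step, {"A": 0.0, "B": 0.0}, {"A": "H2O", "B": "H2S"})


# --------------------------------------------------------------- barriers


def test_forward_and_reverse_barriers_published(c2):
    """TS at -0.3 over reactants at -19.7: forward 19.4; over products at
    -19.2: reverse 18.9. Their difference is the step dG."""
    steps, table, _ = c2
    assert barrier(steps[0], table) == pytest.approx(19.4, abs=1e-9)
    assert barrier(steps[0], table, "reverse") == pytest.approx(18.9, abs=1e-9)


def test_barrier_identity_all_ts_steps(c2):
    steps, table, _ = c2
    for step in steps:
        if step.ts is None:
            continue
        assert barrier(step, table) - barrier(step, table, "reverse") == pytest.approx(
            reaction_dG(step, table), abs=1e-9
        )


def test_zero_barrier_and_missing_ts():
    table = {"A": -1.0, "B": -2.0}
    step = ElementaryStep(
        ThermoState.of("A"), ThermoState.of("B"),
        TransitionStateNode("TS", -1.0),
    )
    assert barrier(step, table) == 0.0
    bare = ElementaryStep(ThermoState.of("A"), ThermoState.of("B"))
    with pytest.raises(NetworkError):
        barrier(bare, table)


# ------------------------------------------------------------ pathway sums


def test_net_pathway_sugar_to_thioester(c2):
    """Chaining +0.5, -1.4, -21.6 telescopes to the printed -22.5 net."""
    steps, table, _ = c2
    assert net_pathway_dG(steps[:3], table) == pytest.approx(-22.5, abs=1e-9)


def test_net_pathway_c4_stabilization(ref):
    lad = ref.ladder("C4")
    assert lad.net_dG() == pytest.approx(-25.1, abs=1e-9)


def test_cycle_returns_zero(c2):
    steps, table, _ = c2
    cycle = steps[:2] + [s.reversed() for s in reversed(steps[:2])]
    assert net_pathway_dG(cycle, table) == pytest.approx(0.0, abs=1e-12)


def test_non_chaining_pathway_identified():
    table = {"A": 0.0, "B": 1.0, "C": 2.0}
    s1 = ElementaryStep(ThermoState.of("A"), ThermoState.of("B"), label="s1")
    s2 = ElementaryStep(ThermoState.of("C"), ThermoState.of("A"), label="s2")
    with pytest.raises(NetworkError, match="s1"):
        net_pathway_dG([s1, s2], table)
    with pytest.raises(NetworkError):
        net_pathway_dG([], table)


def test_telescoping_property_random_pathways():
    """For random chains the sum of step dG equals the endpoint difference
    at full precision."""
    rng = np.random.default_rng(1234)
    for _ in range(25):
        n = int(rng.integers(2, 12))
        table = {f"s{k}": float(rng.normal(0, 20)) for k in range(n + 1)}
        steps = [
            ElementaryStep(ThermoState.of(f"s{k}"), ThermoState.of(f"s{k+1}"))
            for k in range(n)
        ]
        total = net_pathway_dG(steps, table)
        assert total == pytest.approx(table[f"s{n}"] - table["s0"], abs=1e-9)


# ---------------------------------------------------------------- ladders


def test_build_ladder_c2_endpoints_and_alternation(c2):
    steps, table, _ = c2
    lad = build_ladder(steps, table, branch="C2")
    assert lad.states[0].G_rel == pytest.approx(-19.7)
    assert lad.states[-1].G_rel == pytest.approx(-48.2, abs=0.15)
    kinds = [p.kind for p in lad.points]
    assert kinds[0] == "state" and kinds[-1] == "state"


def test_single_step_ladder_three_points():
    table = {"A": 0.0, "B": -3.0}
    step = ElementaryStep(ThermoState.of("A"), ThermoState.of("B"),
                          TransitionStateNode("TS", 5.0))
    lad = build_ladder([step], table)
    assert [p.kind for p in lad.points] == ["state", "ts", "state"]


def test_ladder_coordinates_match_prefix_sums():
    rng = np.random.default_rng(77)
    dGs = rng.normal(0, 5, size=10)
    incs = [(f"x{k}", float(d), 3.0) for k, d in enumerate(dGs)]
    lad = EnergyLadder.from_increments("start", -10.0, incs)
    expected = -10.0 + np.concatenate([[0.0], np.cumsum(dGs)])
    got = [p.G_rel for p in lad.states]
    assert np.allclose(got, expected, atol=1e-12)


def test_ladder_telescoping_invariant(ref):
    for branch, lad in ref.ladders().items():
        assert lad.net_dG() == pytest.approx(sum(lad.step_dGs()), abs=1e-9)


# -------------------------------------------------------------------- RDS


def test_rds_is_dehydration_for_c2(c2):
    """The highest transition state of the C2 ladder belongs to the
    dehydration 2a -> 3, with a forward barrier of 26.0 kcal/mol."""
    steps, table, _ = c2
    lad = build_ladder(steps, table, branch="C2")
    r = find_rds(lad)
    assert r.ts_label == "TS(2a-3)"
    assert r.forward_barrier == pytest.approx(26.0, abs=1e-9)
    assert not r.tied


def test_rds_single_ts_and_no_ts():
    table = {"A": 0.0, "B": -1.0}
    with_ts = ElementaryStep(ThermoState.of("A"), ThermoState.of("B"),
                             TransitionStateNode("only", 4.0))
    lad = build_ladder([with_ts], table)
    assert find_rds(lad).ts_label == "only"
    bare = build_ladder([ElementaryStep(ThermoState.of("A"), ThermoState.of("B"))], table)
    with pytest.raises(NetworkError):
        find_rds(bare)


def test_rds_tie_breaks_earliest_and_reports_tie():
    incs = [("a", -1.0, 10.0), ("b", 0.0, 11.0)]
    # both TS at +10 over a start of 0: second step starts at -1, barrier 11
    lad = EnergyLadder.from_increments("s", 0.0, incs)
    r = find_rds(lad)
    assert r.ts_label == "TS(a)" and r.tied


def test_rds_agrees_with_brute_force_on_random_ladders():
    """1000 random synthetic ladders: the reported RDS is the argmax over
    transition-state G_rel values, compared against a plain max scan."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(1, 10))
        incs = [
            (f"m{k}", float(rng.normal(0, 8)), float(rng.uniform(1, 40)))
            for k in range(n)
        ]
        lad = EnergyLadder.from_increments("s0", float(rng.normal(0, 10)), incs)
        r = find_rds(lad)
        ts = lad.transition_states
        brute = max(range(len(ts)), key=lambda i: ts[i].G_rel)
        assert ts[brute].G_rel == r.ts_G_rel
        assert ts[r.step_index].G_rel == ts[brute].G_rel


def test_planted_rds_recovered_from_generator():
    for seed in (7, 19, 123):
        net = gen_network(seed=seed, n_steps=8, n_branches=2)
        for label, steps in net.branches.items():
            lad = build_ladder(steps, net.table, branch=label)
            assert find_rds(lad).step_index == net.planted_rds[label]


# ------------------------------------------------------------ Hess checks


def test_hess_unknown_route_constraint():
    """Two routes 13a -> 16a: (-6.8 + 4.8) via the enol versus (+0.1 + x)
    via the hemithioacetal pin the unprinted x at -2.1."""
    assert hess_solve_unknown([-6.8, 4.8], [0.1, None]) == pytest.approx(-2.1)


def test_hess_flags_published_13b_branch_pair(ref):
    """The two printed routes 13b -> 16b disagree by 3.0 kcal/mol — a
    genuine inconsistency of the published values, reported not repaired."""
    r = hess_residual([-2.6, 6.8], [2.7, -1.5])
    assert r.residual == pytest.approx(3.0, abs=1e-9)
    assert r.flagged
    incon = ref.known_inconsistencies()
    assert any("13b" in str(entry.get("what", "")) for entry in incon)


def test_hess_residual_within_tolerance_not_flagged():
    r = hess_residual([1.0, -0.5], [0.6, -0.2], tolerance=0.25)
    assert r.residual == pytest.approx(0.1)
    assert not r.flagged


def test_hess_network_cycles_close_on_synthetic_data():
    """A branched network whose state energies come from one G_rel table
    closes every cycle to numerical precision."""
    net = gen_network(seed=5, n_steps=6, n_branches=3)
    steps = [s for b in net.branches.values() for s in b]
    # tie the branch ends together to create cycles
    ends = [b[-1].products for b in net.branches.values()]
    for a, b in zip(ends, ends[1:]):
        steps.append(ElementaryStep(a, b, label=f"tie:{b}"))
    results = hess_check_network(steps, net.table, tolerance=1e-9)
    assert results, "tied branches must produce at least one cycle"
    for labels, residual, flagged in results:
        assert abs(residual) < 1e-9 and not flagged


def test_hess_network_flags_declared_inconsistency():
    """Feeding independently declared (rounded) step dG values that violate
    closure produces a flagged cycle residual."""
    a, b, c = ThermoState.of("A"), ThermoState.of("B"), ThermoState.of("C")
    steps = [
        ElementaryStep(a, b, label="A->B"),
        ElementaryStep(b, c, label="B->C"),
        ElementaryStep(a, c, label="A->C"),
    ]
    declared = {"A->B": -2.6, "B->C": 6.8, "A->C": 1.2}
    results = hess_check_network(steps, declared_dG=declared, tolerance=0.25)
    assert len(results) == 1
    _, residual, flagged = results[0]
    assert abs(residual) == pytest.approx(3.0, abs=1e-9) and flagged


# ---------------------------------------------------------- export / I/O


def test_export_diagram_roundtrip(ref, tmp_path):
    ladders = [ref.ladder(b) for b in ("C3", "C3-thiol", "C3-thiol-h2s")]
    out = tmp_path / "diagram.csv"
    frame = export_diagram(ladders, csv_path=out, plot_path=tmp_path / "diagram.svg")
    assert sorted(frame["branch"].unique()) == ["C3", "C3-thiol", "C3-thiol-h2s"]
    assert (tmp_path / "diagram.svg").exists()
    import pandas as pd

    reloaded = pd.read_csv(out)
    for branch in ("C3", "C3-thiol"):
        lad = ladder_from_frame(reloaded, branch)
        orig = next(l for l in ladders if l.branch == branch)
        assert [p.G_rel for p in lad.points] == pytest.approx(
            [p.G_rel for p in orig.points]
        )
    with pytest.raises(NetworkError):
        export_diagram([])


def test_single_point_ladder_exports_one_row():
    from thiopath.network import LadderPoint

    lad = EnergyLadder([LadderPoint("state", "x", -1.0)])
    assert len(export_diagram([lad])) == 1


def test_network_yaml_roundtrip(c2):
    steps, table, _ = c2
    text = dump_network({"C2": steps})
    branches = load_network(io.StringIO(text))
    assert list(branches) == ["C2"]
    again = branches["C2"]
    assert [s.label for s in again] == [s.label for s in steps]
    assert net_pathway_dG(again, table) == pytest.approx(
        net_pathway_dG(steps, table), abs=1e-12
    )
    assert again[0].ts.G_rel == steps[0].ts.G_rel


def test_load_network_rejects_malformed():
    with pytest.raises(NetworkError):
        load_network(io.StringIO("species: [a]\n"))
    with pytest.raises(NetworkError):
        load_network(io.StringIO("branches:\n  - label: empty\n    steps: []\n"))


def test_compare_branches_prefers_low_ts_and_low_net(ref):
    frame = compare_branches([ref.ladder("C3"), ref.ladder("C3-thiol")])
    assert frame["kinetically_preferred"].sum() == 1
    assert frame["thermodynamically_preferred"].sum() == 1
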