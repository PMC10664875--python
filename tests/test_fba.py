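"""FBA / pFBA solver behavior, with cobrapy as an independent oracle."""

import numpy as np
import pytest

import metapgs as mp
from metapgs.environments import Medium
from metapgs.fba import (
    FluxSolution,
    fba,
    pfba,
    population_flux_stats,
    unused_flux_fraction,
)
from metapgs.grr import GeneRef
from metapgs.model import MetabolicNetwork, Metabolite, Reaction, to_cobra
from metapgs.mutations import apply_dosages


def test_toy3_hand_lp(toy3_scenario):
    """Wild type grows at min(10, 10, 10) = 10; g1 = 0.6 caps it at 6."""
    sc = toy3_scenario
    wt = apply_dosages(sc.network, sc.ref, {"g1": 1, "g2": 1, "g3": 1})
    assert fba(wt, sc.medium).growth == pytest.approx(10.0, abs=1e-8)
    mut = apply_dosages(sc.network, sc.ref, {"g1": 0.6, "g2": 1, "g3": 1})
    assert fba(mut, sc.medium).growth == pytest.approx(6.0, abs=1e-8)


def test_closed_medium_zero_growth(toy3_scenario):
    sol = fba(toy3_scenario.network, Medium({}))
    assert sol.feasible and sol.growth == pytest.approx(0.0, abs=1e-9)


def test_infeasible_flagged():
    """A forced maintenance flux with all imports closed is infeasible,
    which is distinguished from a feasible zero-growth optimum."""
    mets = [Metabolite("a_e", "", "e"), Metabolite("b_c", "", "c")]
    rxns = [
        Reaction("EX_a", {"a_e": -1}, 0, 1000, rxn_class="exchange"),
        Reaction("R1", {"a_e": -1, "b_c": 1}, 0, 1000),
        Reaction("FORCED", {"b_c": -1}, 5, 5, rxn_class="atp-maintenance"),
        Reaction("BIO", {"b_c": -1}, 0, 1000, rxn_class="biomass"),
    ]
    net = MetabolicNetwork(mets, rxns)
    sol = pfba(net, Medium({}))
    assert not sol.feasible and sol.growth == 0.0
    assert pfba(net, Medium({"EX_a": 10})).feasible


def test_mass_balance_and_bounds(mixed_chain_scenario, rng):
    sc = mixed_chain_scenario
    S = sc.network.stoichiometric_matrix()
    for _ in range(10):
        d = {g: rng.uniform(0.2, 1.0) for g in sc.genes}
        bm = apply_dosages(sc.network, sc.ref, d)
        sol = pfba(bm, sc.medium)
        assert sol.feasible
        assert np.max(np.abs(S @ sol.fluxes)) < 1e-6


def test_pfba_matches_fba_growth_and_is_parsimonious(toy3_scenario):
    sc = toy3_scenario
    a = fba(sc.network, sc.medium)
    b = pfba(sc.network, sc.medium)
    assert b.growth == pytest.approx(a.growth, rel=1e-6)
    assert b.total_abs_flux <= a.total_abs_flux + 1e-6


def test_pfba_single_path_routing():
    """Two redundant routes (direct, or via an intermediate): both reach the
    same growth, but the enumerated minimal-total-flux optimum uses only the
    direct path (total |v| = 30, not 40)."""
    mets = [Metabolite("a_e", "", "e"), Metabolite("b_c", "", "c"), Metabolite("x_c", "", "c")]
    rxns = [
        Reaction("EX_a", {"a_e": -1}, 0, 1000, rxn_class="exchange"),
        Reaction("Rdirect", {"a_e": -1, "b_c": 1}, 0, 1000),
        Reaction("Rs1", {"a_e": -1, "x_c": 1}, 0, 1000),
        Reaction("Rs2", {"x_c": -1, "b_c": 1}, 0, 1000),
        Reaction("BIO", {"b_c": -1}, 0, 1000, rxn_class="biomass"),
    ]
    sol = pfba(MetabolicNetwork(mets, rxns), Medium({"EX_a": 10}))
    assert sol.growth == pytest.approx(10.0, abs=1e-7)
    assert sol.total_abs_flux == pytest.approx(30.0, abs=1e-5)
    assert abs(sol.flux("Rs1")) < 1e-7


def test_growth_invariant_to_reaction_order(toy3_scenario):
    sc = toy3_scenario
    net = sc.network
    shuffled = MetabolicNetwork(
        net.metabolites, list(reversed(net.reactions)), genes=net.genes, id="shuffled"
    )
    assert pfba(shuffled, sc.medium).growth == pytest.approx(
        pfba(net, sc.medium).growth, abs=1e-9
    )


def test_cross_check_against_cobrapy(toy3_scenario):
    """Independent oracle: cobrapy's own pFBA (GLPK) on the identical
    dosage-bounded toy agrees on growth and total flux."""
    cobra_fa = pytest.importorskip("cobra.flux_analysis")
    sc = toy3_scenario
    dosages = {"g1": 0.8, "g2": 0.4, "g3": 0.3}
    bm = apply_dosages(sc.network, sc.ref, dosages)
    ours = pfba(bm, sc.medium)

    cm = to_cobra(sc.network)
    for i, rxn in enumerate(sc.network.reactions):
        cr = cm.reactions.get_by_id(rxn.id)
        if rxn.rxn_class == "exchange":
            cr.lower_bound = -sc.medium.imports.get(rxn.id, 0.0)
        else:
            cr.lower_bound, cr.upper_bound = float(bm.lb[i]), float(bm.ub[i])
    theirs = cobra_fa.pfba(cm)
    assert ours.growth == pytest.approx(theirs.fluxes["BIOMASS"], abs=1e-6)
    assert ours.total_abs_flux == pytest.approx(theirs.fluxes.abs().sum(), abs=1e-5)


def test_unused_flux_fraction(toy3_scenario):
    sol = pfba(toy3_scenario.network, toy3_scenario.medium)
    assert unused_flux_fraction(sol) == 0.0  # all 4 reactions carry flux
    fake = FluxSolution(["a", "b", "c", "d"], np.array([0.0, 0.0, 0.0, 5.0]), 5.0, "optimal", 5.0)
    assert unused_flux_fraction(fake) == pytest.approx(0.75)


def test_population_flux_stats(toy3_scenario):
    sc = toy3_scenario
    sols = [
        pfba(apply_dosages(sc.network, sc.ref, {"g1": g, "g2": 1, "g3": 1}), sc.medium)
        for g in (0.8, 1.2 / 1.2, 0.9)
    ]
    stats = population_flux_stats(sols)
    # chain topology forces proportional flux vectors
    assert np.all(stats["correlation_with_mean"] > 1 - 1e-9)

    two = [
        FluxSolution(["r"], np.array([8.0]), 0, "optimal", 8.0),
        FluxSolution(["r"], np.array([12.0]), 0, "optimal", 12.0),
    ]
    # degenerate one-reaction case: mean 10, CV = sigma/mu = 0.2
    s = population_flux_stats(two)
    assert s["mean_flux"]["r"] == pytest.approx(10.0)
    assert s["cv"]["r"] == pytest.approx(0.2)

    same = [sols[0], sols[0]]
    assert np.nanmax(population_flux_stats(same)["cv"].to_numpy()) == pytest.approx(0.0)
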