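"""Dosage -> bound mapping and the evolutionary-history reference ensemble."""

import numpy as np
import pytest

import metapgs as mp
from metapgs.environments import Medium
from metapgs.fba import fba, pfba
from metapgs.grr import GeneRef, OrRule
from metapgs.model import MetabolicNetwork, Metabolite, Reaction
from metapgs.mutations import ReferenceBounds, apply_dosages, compute_reference_bounds


def test_apply_dosages_identity(toy3_scenario):
    """All dosages 1 reproduce the reference bounds exactly."""
    sc = toy3_scenario
    bm = apply_dosages(sc.network, sc.ref, {g: 1.0 for g in sc.genes})
    for rxn_id, ub in sc.ref.upper.items():
        i = sc.network.reaction_index(rxn_id)
        assert bm.ub[i] == pytest.approx(ub)
        assert bm.lb[i] == pytest.approx(sc.ref.lower.get(rxn_id, 0.0))


def test_apply_dosages_or_scaling(toy3_scenario):
    """OR(g2=0.3, g3=0.2) with f_ub = 10 gives an upper bound of 5."""
    sc = toy3_scenario
    bm = apply_dosages(sc.network, sc.ref, {"g1": 1.0, "g2": 0.3, "g3": 0.2})
    i = sc.network.reaction_index("R2")
    assert bm.ub[i] == pytest.approx(5.0)
    assert fba(bm, sc.medium).growth == pytest.approx(5.0)


def test_apply_dosages_reversible_scaling():
    """delta = 0.4 on a reversible reaction with f_lb = -8 gives lb = -3.2."""
    mets = [Metabolite("a_e", "", "e"), Metabolite("b_c", "", "c")]
    rxns = [
        Reaction("EX_a", {"a_e": -1}, 0, 1000, rxn_class="exchange"),
        Reaction("R1", {"a_e": -1, "b_c": 1}, -1000, 1000, grr=GeneRef("g1")),
        Reaction("BIO", {"b_c": -1}, 0, 1000, rxn_class="biomass"),
    ]
    net = MetabolicNetwork(mets, rxns)
    ref = ReferenceBounds({"R1": -8.0}, {"R1": 10.0})
    bm = apply_dosages(net, ref, {"g1": 0.4})
    i = net.reaction_index("R1")
    assert bm.lb[i] == pytest.approx(-3.2)
    assert bm.ub[i] == pytest.approx(4.0)


def test_exempt_classes_keep_model_bounds(toy3_scenario):
    sc = toy3_scenario
    bm = apply_dosages(sc.network, sc.ref, {"g1": 0.2, "g2": 0.2, "g3": 0.2})
    for rxn in sc.network.reactions:
        if rxn.rxn_class != "internal":
            i = sc.network.reaction_index(rxn.id)
            assert bm.lb[i] == rxn.lower_bound
            assert bm.ub[i] == rxn.upper_bound


def test_reference_bounds_match_ensemble_extremes(toy3_scenario):
    """With a degenerate bound range the ensemble is deterministic, so the
    reference upper bound must equal the maximum flux over the explicitly
    re-solved ensemble."""
    sc = toy3_scenario
    rates = np.random.default_rng(0).uniform(0, 20, 12)
    media = [Medium({"EX_nut": float(r)}, name=f"m{i}") for i, r in enumerate(rates)]
    B = 7.0
    ref = compute_reference_bounds(
        sc.network, n_media=len(media), bound_range=(B, B), rng_seed=9, media=media
    )
    # oracle: re-solve the same pairs directly
    lb0, ub0 = sc.network.default_bounds()
    capped_lb, capped_ub = lb0.copy(), ub0.copy()
    for i, rxn in enumerate(sc.network.reactions):
        if rxn.rxn_class == "internal":
            capped_ub[i] = B
    expected = {r.id: 0.0 for r in sc.network.reactions if r.rxn_class == "internal"}
    for medium in media:
        for inst in (sc.network, mp.fba.BoundedModel(sc.network, capped_lb, capped_ub)):
            sol = pfba(inst, medium)
            for rxn_id in expected:
                expected[rxn_id] = max(expected[rxn_id], sol.flux(rxn_id))
    for rxn_id, exp in expected.items():
        assert ref.upper[rxn_id] == pytest.approx(exp, abs=1e-7)
    # exempt reactions never enter the reference table
    assert "EX_nut" not in ref.upper and "BIOMASS" not in ref.upper
    assert ref.provenance["n_solutions"] == 2 * len(media)


def test_never_active_reaction_closed():
    """A dead-end side reaction carries no flux in any ensemble solution,
    so its reference bound is 0 and it stays permanently closed."""
    mets = [
        Metabolite("a_e", "", "e"),
        Metabolite("b_c", "", "c"),
        Metabolite("dead_c", "", "c"),
    ]
    rxns = [
        Reaction("EX_a", {"a_e": -1}, 0, 1000, rxn_class="exchange"),
        Reaction("R1", {"a_e": -1, "b_c": 1}, 0, 1000, grr=GeneRef("g1")),
        Reaction("Rdead", {"a_e": -1, "dead_c": 1}, 0, 1000, grr=GeneRef("g2")),
        Reaction("BIO", {"b_c": -1}, 0, 1000, rxn_class="biomass"),
    ]
    net = MetabolicNetwork(mets, rxns)
    media = [Medium({"EX_a": 5.0}), Medium({"EX_a": 15.0})]
    ref = compute_reference_bounds(net, n_media=2, bound_range=(50, 50), media=media)
    assert ref.upper["Rdead"] == 0.0
    assert ref.upper["R1"] > 0


def test_growth_monotone_in_dosage(mixed_chain_scenario, rng):
    """Pairwise dominance: lowering any subset of dosages never raises
    growth (bounds only tighten)."""
    sc = mixed_chain_scenario
    for _ in range(60):
        high = {g: rng.uniform(0.3, 1.0) for g in sc.genes}
        low = {g: v * rng.uniform(0.5, 1.0) for g, v in high.items()}
        g_hi = fba(apply_dosages(sc.network, sc.ref, high), sc.medium).growth
        g_lo = fba(apply_dosages(sc.network, sc.ref, low), sc.medium).growth
        assert g_lo <= g_hi + 1e-7


def test_wildtype_dominance(toy3_scenario, rng):
    sc = toy3_scenario
    g_wt = fba(apply_dosages(sc.network, sc.ref, {g: 1.0 for g in sc.genes}), sc.medium).growth
    for _ in range(25):
        d = {g: rng.uniform(0, 1) for g in sc.genes}
        assert fba(apply_dosages(sc.network, sc.ref, d), sc.medium).growth <= g_wt + 1e-7


def test_reference_bounds_tsv_roundtrip(toy3_scenario, tmp_path):
    sc = toy3_scenario
    p, pj = tmp_path / "ref.tsv", tmp_path / "ref.json"
    sc.ref.to_tsv(p, provenance_path=pj)
    back = ReferenceBounds.from_tsv(p, provenance_path=pj)
    assert back.upper == sc.ref.upper
    assert back.lower == sc.ref.lower
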