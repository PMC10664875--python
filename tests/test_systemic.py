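"""Pleiotropy, precursor contributions, dosage response, bound manipulation."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import metapgs as mp
from metapgs.exceptions import ConfigError
from metapgs.fba import pfba
from metapgs.mutations import apply_dosages
from metapgs.systemic import (
    coupling_experiment,
    dosage_response,
    growth_cost_matrix,
    manipulate_reference_bounds,
    pleiotropic_impact,
    pleiotropy,
    precursor_contribution,
)


@pytest.fixture(scope="module")
def branched_subset(branched_scenario):
    G, _ = mp.scenario_dataset(branched_scenario, 5, sigma=0.1, seed=3)
    return G


@pytest.fixture(scope="module")
def branched_pleiotropy(branched_scenario, branched_subset):
    sc = branched_scenario
    return pleiotropy(sc.network, sc.ref, branched_subset, sc.medium)


def test_pleiotropy_counts(branched_scenario, branched_pleiotropy):
    """The shared upstream enzyme limits every precursor's producibility
    under a 90% knockdown; each branch enzyme limits only its own."""
    pl = branched_pleiotropy
    assert pl.mean["g0"] == pytest.approx(3.0)
    for i in (1, 2, 3):
        assert pl.mean[f"b{i}"] == pytest.approx(1.0)
        frac = pl.affect_fraction.loc[f"b{i}"]
        assert frac[f"p{i}_c"] == 1.0
        assert frac.drop(f"p{i}_c").max() == 0.0
    # significance threshold spans the gene-score distribution
    assert pl.mean.max() >= pl.significance_threshold() >= pl.mean.min()


def test_pleiotropy_hand_lp(branched_scenario):
    """Hand-checkable export LPs: with upstream ref = uptake = 10, a 90%
    knockdown of g0 caps each precursor's export at 1 (= 10 * 0.1 * g0)."""
    sc = branched_scenario
    wt = {g: 1.0 for g in sc.genes}
    inst = apply_dosages(sc.network, sc.ref, wt)
    base = mp.fba.maximize_metabolite_export(inst, "p2_c", sc.medium)
    # B2 reference bound: c2 * y_wt = 2 * 10/6
    assert base == pytest.approx(2 * 10 / 6, abs=1e-7)
    kd = dict(wt, g0=0.1)
    dropped = mp.fba.maximize_metabolite_export(
        apply_dosages(sc.network, sc.ref, kd), "p2_c", sc.medium
    )
    assert dropped == pytest.approx(1.0, abs=1e-7)


def test_pleiotropic_impact_planted(branched_pleiotropy):
    """A 'strong' set {g0, b1} hits p1 via two members but p2/p3 via one,
    so p1 carries the largest z-score; random sets give z ~ 0 on average."""
    z = pleiotropic_impact(branched_pleiotropy, ["g0", "b1"], n_null=1000, seed=1)
    assert z.loc["p1_c", "z"] == z["z"].max()
    rng = np.random.default_rng(5)
    genes = list(branched_pleiotropy.affect_fraction.index)
    zs = []
    for _ in range(40):
        pick = list(rng.choice(genes, size=2, replace=False))
        zs.append(pleiotropic_impact(branched_pleiotropy, pick, n_null=400, seed=2)["z"].mean())
    assert abs(np.mean(zs)) < 0.5


def test_precursor_contribution_sole_producer(branched_scenario, branched_subset):
    sc = branched_scenario
    sols = [
        pfba(apply_dosages(sc.network, sc.ref, branched_subset.row(i)), sc.medium)
        for i in range(len(branched_subset))
    ]
    xi = precursor_contribution(sc.network, sols, ["b1"], n_randomizations=200, seed=0)
    # b1's reaction is the only producer of p1: xi = 100% of biomass demand
    assert xi.loc["p1_c", "xi"] == pytest.approx(100.0, abs=1e-6)
    assert xi.loc["p2_c", "xi"] == pytest.approx(0.0, abs=1e-9)

    empty = precursor_contribution(sc.network, sols, [], n_randomizations=50, seed=0)
    assert np.allclose(empty["xi"], 0.0)

    # monotone in set inclusion
    xi_all = precursor_contribution(sc.network, sols, sc.genes, n_randomizations=50, seed=0)
    assert (xi_all["xi"].to_numpy() >= xi["xi"].to_numpy() - 1e-9).all()


def test_dosage_response_profiles(toy3_scenario):
    """g1 sweeps: growth = 10*min(g1, clip(g2+g3, 1)) gives a piecewise-
    linear profile with the breakpoint where g1 stops limiting; the gene
    is essential (zero growth at g = 0)."""
    sc = toy3_scenario
    bg = mp.GenotypeMatrix(np.array([[0.9, 0.5, 0.35], [0.8, 1.0, 1.0]]), sc.genes)
    out = dosage_response(sc.network, sc.ref, "g1", bg, sc.medium, grid=np.linspace(0, 1, 11))
    assert out["essential"] is True
    grid = out["grid"]
    np.testing.assert_allclose(out["profiles"][0], 10 * np.minimum(grid, 0.85), atol=1e-7)
    np.testing.assert_allclose(out["profiles"][1], 10 * grid, atol=1e-7)


def test_dosage_response_flat_for_cryptic_gene():
    sc = mp.toy_chain(length=2, ref_slack={1: 1.0, 2: 2.0})
    bg = mp.GenotypeMatrix(np.array([[0.9, 0.95]]), sc.genes)
    out = dosage_response(sc.network, sc.ref, "g2", bg, sc.medium, grid=np.linspace(0.5, 1.0, 6))
    # above dosage 0.45 the slack-2 step never limits: profile is constant
    assert np.ptp(out["profiles"][0]) < 1e-9


def test_growth_cost_matrix(toy3_scenario):
    sc = toy3_scenario
    G = mp.GenotypeMatrix(np.array([[0.9, 0.6, 0.3], [0.5, 1.0, 1.0]]), sc.genes)
    costs = growth_cost_matrix(sc.network, sc.ref, G, sc.medium, knockdown=0.9)
    # analytic: growth = 10*min(g1, clip(g2+g3,1)); knockdown scales one dosage by 0.1
    for j in range(2):
        g1, g2, g3 = G.values[j]
        base = 10 * min(g1, min(1.0, g2 + g3))
        exp_g1 = (base - 10 * min(0.1 * g1, min(1.0, g2 + g3))) / base
        assert costs.iloc[:, j]["g1"] == pytest.approx(exp_g1, abs=1e-7)
        exp_g2 = (base - 10 * min(g1, min(1.0, 0.1 * g2 + g3))) / base
        assert costs.iloc[:, j]["g2"] == pytest.approx(exp_g2, abs=1e-7)


def test_manipulate_reference_bounds(toy3_scenario, toy3_dataset):
    sc = toy3_scenario
    G, y = toy3_dataset

    # identity edit: same phenotypes, same PGS
    same = manipulate_reference_bounds(sc.ref, {"R1": 1.0}, sc.network)
    y_same = mp.population_phenotypes(sc.network, same, G, sc.medium)
    np.testing.assert_allclose(y_same, y, atol=1e-8)

    # raising the limiting reaction's bound 10x turns g1's variation
    # cryptic: growth flattens at the uptake/isozyme ceiling, so either the
    # phenotype is outright constant or g1's effect collapses to ~0
    raised = manipulate_reference_bounds(sc.ref, {"R1": ("scale", 10.0)}, sc.network)
    y_raised = mp.population_phenotypes(sc.network, raised, G, sc.medium)
    try:
        m = mp.train_pgs(G, y_raised, seed=0, compute_cv_r2=False)
        assert abs(m.beta["g1"]) < 0.5
    except mp.pgs.DegenerateFitError:
        np.testing.assert_allclose(y_raised, y_raised[0])

    with pytest.raises(ConfigError):  # exchanges are exempt
        manipulate_reference_bounds(sc.ref, {"EX_nut": 2.0}, sc.network)
    with pytest.raises(ConfigError):
        manipulate_reference_bounds(sc.ref, {"NOPE": 2.0}, sc.network)


def test_lowering_a_cryptic_bound_creates_a_predictor():
    """The converse manipulation: dropping the reference bound of a
    slack-2 (cryptic) single-gene reaction below the functional flux
    makes its gene the dominant growth predictor."""
    sc = mp.toy_chain(length=2, ref_slack={1: 1.0, 2: 2.0})
    G, y = mp.scenario_dataset(sc, 200, sigma=0.1, seed=1, lp_check=10)
    base = mp.train_pgs(G, y, seed=0, compute_cv_r2=False)
    assert base.beta.abs().idxmax() == "g1"
    assert abs(base.beta["g2"]) < 0.5

    lowered = manipulate_reference_bounds(sc.ref, {"R2": ("scale", 0.3)}, sc.network)
    y_low = mp.population_phenotypes(sc.network, lowered, G, sc.medium)
    m2 = mp.train_pgs(G, y_low, seed=0, compute_cv_r2=False)
    assert m2.beta.abs().idxmax() == "g2"
    assert m2.beta["g2"] > 0.5


def test_coupling_experiment_sign():
    """Coupling (scaling reference bounds down) creates new limiting
    reactions: more strong predictors, lower R^2 — negative rank
    correlation across the sweep; zero iterations yield the baseline only."""
    sc = mp.toy_chain(length=5, ref_slack={1: 1.0, 2: 2.0, 3: 2.0, 4: 2.0, 5: 2.0})
    G, y = mp.scenario_dataset(sc, 150, sigma=0.15, seed=4, lp_check=10)
    base_only = coupling_experiment(
        sc.network, sc.ref, G, sc.medium, n_iterations=0, threshold=0.2
    )
    assert len(base_only) == 1 and base_only.iloc[0]["manipulation"] == "baseline"

    table = coupling_experiment(
        sc.network, sc.ref, G, sc.medium, n_iterations=10,
        group_size_range=(1, 3), seed=3, threshold=0.2,
    )
    assert (table["manipulation"] == "baseline").sum() == 1
    ok = table.dropna(subset=["r2"])
    rho = spearmanr(ok["n_strong"], ok["r2"]).statistic
    assert rho < 0
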