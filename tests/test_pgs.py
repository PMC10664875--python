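"""Polygenic-score fitting, classification, theta_max, portability."""

import numpy as np
import pandas as pd
import pytest

import metapgs as mp
from metapgs.environments import Medium
from metapgs.exceptions import AlignmentError, DegenerateFitError
from metapgs.pgs import (
    PGSModel,
    classify_effects,
    overfitting_assessment,
    portability_experiment,
    predict,
    r_squared,
    theta_max,
    train_pgs,
)
from metapgs.population import GenotypeMatrix


def _linear_data(n=80, m=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, m))
    beta = np.array([2.0, -1.0, 0.5, 0.0])
    y = X @ beta + 0.3 + noise * rng.normal(size=n)
    return X, y, beta


def test_ols_exact_recovery():
    X, y, beta = _linear_data()
    model = train_pgs(X, y, method="ols")
    assert model.r2_train == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(model.beta.to_numpy(), beta, atol=1e-8)
    assert model.intercept == pytest.approx(0.3, abs=1e-8)


def test_lasso_produces_exact_zeros(toy3_dataset):
    G, y = toy3_dataset
    model = train_pgs(G, y, seed=0)
    assert (model.beta == 0.0).sum() >= 1
    # growth = 10*min(g1, clip(g2+g3,1)): g1 limits, the isozymes never do
    assert model.beta["g1"] > 5.0
    assert abs(model.beta["g2"]) < 0.2 and abs(model.beta["g3"]) < 0.2


def test_lasso_converges_to_ols_at_zero_shrinkage():
    X, y, _ = _linear_data(noise=0.05, seed=3)
    ols = train_pgs(X, y, method="ols", compute_cv_r2=False)
    from sklearn.linear_model import Lasso

    mu, sd = X.mean(0), X.std(0)
    tiny = Lasso(alpha=1e-10, max_iter=2_000_000, tol=1e-14).fit((X - mu) / sd, y)
    beta_tiny = tiny.coef_ / sd
    assert np.max(np.abs(beta_tiny - ols.beta.to_numpy())) < 1e-4


def test_ols_r2_dominates_penalized(toy3_dataset):
    G, y = toy3_dataset
    r2_ols = train_pgs(G, y, method="ols", compute_cv_r2=False).r2_train
    for method in ("lasso", "ridge", "elasticnet"):
        assert r2_ols >= train_pgs(G, y, method=method, compute_cv_r2=False).r2_train - 1e-10


def test_predict_definitional(toy3_dataset):
    G, y = toy3_dataset
    model = train_pgs(G, y, seed=0, compute_cv_r2=False)
    assert r_squared(y, predict(model, G)) == pytest.approx(model.r2_train)
    # constant predictions never beat the mean
    assert r_squared(y, np.full_like(y, y.mean() + 0.3)) <= 0


def test_predict_aligns_by_gene_id(toy3_dataset):
    G, y = toy3_dataset
    model = train_pgs(G, y, seed=0, compute_cv_r2=False)
    df = G.to_frame()[["g3", "g1", "g2"]]  # permuted columns
    np.testing.assert_allclose(predict(model, df), predict(model, G), atol=1e-12)
    with pytest.raises(AlignmentError):
        predict(model, df.rename(columns={"g1": "other"}))


def test_constant_phenotype_errors():
    X = np.random.default_rng(0).uniform(0, 1, (30, 3))
    with pytest.raises(DegenerateFitError):
        train_pgs(X, np.ones(30))


def test_classify_effects():
    model = PGSModel(
        beta=pd.Series({"a": 0.0, "b": 0.005, "c": 0.02}),
        intercept=0.0, method="lasso", shrinkage=None, r2_train=0.5,
    )
    cl = classify_effects(model, threshold=0.01)
    assert cl.classes.to_dict() == {"a": "null", "b": "weak", "c": "strong"}
    assert cl.counts == {"null": 1, "weak": 1, "strong": 1}
    # invariant to gene permutation
    perm = PGSModel(model.beta[["c", "a", "b"]], 0.0, "lasso", None, 0.5)
    assert classify_effects(perm, 0.01).counts == cl.counts


def test_theta_max():
    model = PGSModel(
        beta=pd.Series([1.0, 0, 0, 0, 0]), intercept=0, method="ols",
        shrinkage=None, r2_train=1.0,
    )
    # mean 0.2, population sd 0.4 -> z = 2 exactly
    assert theta_max(model) == pytest.approx(2.0)
    flat = PGSModel(pd.Series([0.3, 0.3, 0.3]), 0, "ols", None, 1.0)
    assert np.isnan(theta_max(flat))


def test_overfitting_assessment_identity(toy3_dataset):
    G, y = toy3_dataset
    model = train_pgs(G, y, seed=0, compute_cv_r2=False)
    out = overfitting_assessment(model, [(G, y), (G, y)])
    assert out["mean"] == pytest.approx(model.r2_train)
    assert out["sd"] == pytest.approx(0.0, abs=1e-12)


def test_portability_collapse_without_limiting_nutrient():
    """A PGS trained where substrate 1 feeds growth transfers perfectly to
    its own medium but collapses (negative R^2, zero predictor overlap) in
    a medium fed by substrate 2."""
    sc = mp.toy_chain(length=2, ref_slack={1: 2.0, 2: 2.0}, n_substrates=2)
    G, _ = mp.scenario_dataset(sc, 120, sigma=0.1, seed=7, lp_check=10)
    med_a = Medium({"EX_sub1": 10.0}, name="A")
    med_b = Medium({"EX_sub2": 10.0}, name="B")
    y_a = mp.population_phenotypes(sc.network, sc.ref, G, med_a)
    model_a = train_pgs(G, y_a, seed=0, compute_cv_r2=False)
    table = portability_experiment(
        model_a, sc.network, sc.ref, G, [med_a, med_b], med_a, threshold=0.5
    )
    row_a = table[table.medium == "A"].iloc[0]
    row_b = table[table.medium == "B"].iloc[0]
    assert row_a.r2_transfer == pytest.approx(model_a.r2_train)
    assert row_a.overlap == row_a.n_strong_medium >= 1
    assert row_b.r2_transfer < 0
    assert row_b.overlap == 0


def test_cv_r2_close_to_train_r2_on_clean_signal(toy3_dataset):
    G, y = toy3_dataset
    model = train_pgs(G, y, seed=0)
    assert model.cv_r2_mean == pytest.approx(model.r2_train, abs=0.05)
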