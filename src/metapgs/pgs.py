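"""Polygenic scores for growth: y = G beta + intercept + noise.

Effect sizes beta (1/h per unit relative dosage) are estimated by
penalized linear regression — LASSO by default, with the shrinkage
parameter chosen by 5-fold cross-validation — on the genotype matrix G
of relative dosages.  Predictors are standardized internally for the
penalized fits and the coefficients back-transformed to the dosage
scale, so the conventional |beta| > 0.01 1/h threshold for "strong"
predictors applies directly.  OLS, ridge and elastic net are available
as alternative fitters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV, Ridge, RidgeCV
from sklearn.model_selection import KFold

from . import environments as env_mod
from . import mutations as mut_mod
from .exceptions import AlignmentError, ConfigError, DegenerateFitError
from .population import GenotypeMatrix

__all__ = [
    "PGSModel",
    "EffectClassification",
    "train_pgs",
    "predict",
    "r_squared",
    "classify_effects",
    "theta_max",
    "overfitting_assessment",
    "portability_experiment",
]

#: Coefficients below this magnitude are treated as exactly null.
NULL_TOL = 1e-12
#: Conventional strong-predictor threshold (1/h per unit dosage).
STRONG_THRESHOLD = 0.01


@dataclass
class PGSModel:
    """A fitted polygenic score: per-gene effect sizes plus diagnostics."""

    beta: pd.Series  # indexed by gene id, on the dosage scale
    intercept: float
    method: str
    shrinkage: Optional[Dict[str, float]]
    r2_train: float
    cv_r2_mean: Optional[float] = None
    cv_r2_sd: Optional[float] = None
    n_train: int = 0

    @property
    def genes(self) -> List[str]:
        return list(self.beta.index)

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "shrinkage": self.shrinkage,
            "intercept": self.intercept,
            "r2_train": self.r2_train,
            "cv_r2_mean": self.cv_r2_mean,
            "cv_r2_sd": self.cv_r2_sd,
            "n_train": self.n_train,
            "beta": {g: float(b) for g, b in self.beta.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class EffectClassification:
    """Partition of genes into null / weak / strong effect classes."""

    classes: pd.Series  # gene -> {"null", "weak", "strong"}
    threshold: float

    @property
    def counts(self) -> Dict[str, int]:
        base = {"null": 0, "weak": 0, "strong": 0}
        base.update(self.classes.value_counts().to_dict())
        return base

    @property
    def fractions(self) -> Dict[str, float]:
        n = len(self.classes)
        return {k: v / n for k, v in self.counts.items()}

    def strong_genes(self) -> List[str]:
        return list(self.classes.index[self.classes == "strong"])

    def nonnull_genes(self) -> List[str]:
        return list(self.classes.index[self.classes != "null"])


def _as_xy(G: Union[GenotypeMatrix, pd.DataFrame, np.ndarray], y) -> Tuple[np.ndarray, List[str], np.ndarray]:
    if isinstance(G, GenotypeMatrix):
        X, genes = G.values, list(G.genes)
    elif isinstance(G, pd.DataFrame):
        X, genes = G.to_numpy(dtype=float), list(G.columns)
    else:
        X = np.asarray(G, dtype=float)
        genes = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ConfigError("phenotype length does not match genotype rows")
    return X, genes, y


def _make_estimator(method: str, cv, seed: int, n_alphas: int, alpha: Optional[float]):
    if method == "lasso":
        if alpha is not None:
            return Lasso(alpha=alpha, max_iter=100000)
        return LassoCV(alphas=n_alphas, cv=cv, random_state=seed, max_iter=100000)
    if method == "ridge":
        if alpha is not None:
            return Ridge(alpha=alpha)
        return RidgeCV(alphas=np.logspace(-6, 6, n_alphas), cv=cv)
    if method == "elasticnet":
        if alpha is not None:
            return ElasticNet(alpha=alpha, l1_ratio=0.5, max_iter=100000)
        return ElasticNetCV(
            l1_ratio=0.5, alphas=n_alphas, cv=cv, random_state=seed, max_iter=100000
        )
    raise ConfigError(f"unknown PGS method {method!r}")


def train_pgs(
    G: Union[GenotypeMatrix, pd.DataFrame, np.ndarray],
    y,
    method: str = "lasso",
    cv_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 100,
    compute_cv_r2: bool = True,
) -> PGSModel:
    """Fit a PGS; shrinkage (where applicable) chosen by k-fold CV.

    ``r2_train`` is computed on the full training set with the selected
    hyperparameters; ``cv_r2_mean``/``cv_r2_sd`` are the held-out-fold
    R^2 statistics under the same folds.
    """
    X, genes, y = _as_xy(G, y)
    n, m = X.shape
    if np.ptp(y) == 0 or np.var(y) < 1e-24:
        raise DegenerateFitError("phenotype vector is constant")
    if method != "ols" and not (2 <= cv_folds < n):
        raise ConfigError("need n > cv_folds >= 2")

    if method == "ols":
        A = np.column_stack([X, np.ones(n)])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < m + 1:
            warnings.warn("rank-deficient design; returning the least-norm OLS solution")
        beta = coef[:m]
        intercept = float(coef[m])
        shrinkage = None
        folds = KFold(cv_folds, shuffle=True, random_state=seed) if compute_cv_r2 else None
    else:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd_safe
        folds = KFold(cv_folds, shuffle=True, random_state=seed)
        est = _make_estimator(method, folds, seed, n_alphas, alpha=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xs, y)
        alpha = float(getattr(est, "alpha_", np.nan))
        beta = est.coef_ / sd_safe
        intercept = float(est.intercept_ - float(beta @ mu))
        shrinkage = {"alpha": alpha}
        if method == "elasticnet":
            shrinkage["l1_ratio"] = 0.5

    yhat = X @ beta + intercept
    r2_train = r_squared(y, yhat)

    cv_mean = cv_sd = None
    if compute_cv_r2 and folds is not None:
        scores = []
        for train_idx, test_idx in folds.split(X):
            if np.ptp(y[train_idx]) == 0 or np.ptp(y[test_idx]) == 0:
                continue  # fold carries no variance to explain
            sub = train_pgs_fixed(
                X[train_idx], y[train_idx], method,
                alpha=None if shrinkage is None else shrinkage["alpha"],
            )
            scores.append(r_squared(y[test_idx], X[test_idx] @ sub[0] + sub[1]))
        if scores:
            cv_mean = float(np.mean(scores))
            cv_sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else float("nan")

    return PGSModel(
        beta=pd.Series(beta, index=genes, name="beta"),
        intercept=intercept,
        method=method,
        shrinkage=shrinkage,
        r2_train=r2_train,
        cv_r2_mean=cv_mean,
        cv_r2_sd=cv_sd,
        n_train=n,
    )


def train_pgs_fixed(X: np.ndarray, y: np.ndarray, method: str, alpha: Optional[float]):
    """Refit with fixed hyperparameters; returns (beta, intercept)."""
    n, m = X.shape
    if method == "ols":
        A = np.column_stack([X, np.ones(n)])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        return coef[:m], float(coef[m])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    est = _make_estimator(method, None, 0, 1, alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit((X - mu) / sd_safe, y)
    beta = est.coef_ / sd_safe
    return beta, float(est.intercept_ - float(beta @ mu))


def predict(model: PGSModel, G: Union[GenotypeMatrix, pd.DataFrame, np.ndarray]) -> np.ndarray:
    """Predicted phenotypes G beta + intercept; genes aligned by id."""
    if isinstance(G, GenotypeMatrix):
        frame = G.to_frame()
    elif isinstance(G, pd.DataFrame):
        frame = G
    else:
        X = np.asarray(G, dtype=float)
        if X.shape[1] != len(model.beta):
            raise AlignmentError("gene count mismatch for unlabeled genotype array")
        return X @ model.beta.to_numpy() + model.intercept
    missing = [g for g in model.genes if g not in frame.columns]
    if missing:
        raise AlignmentError(f"genotypes lack genes {missing[:5]}...")
    X = frame[model.genes].to_numpy(dtype=float)
    return X @ model.beta.to_numpy() + model.intercept


def r_squared(y_true, y_pred) -> float:
    """Plain coefficient of determination (may be negative on transfer)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0:
        raise DegenerateFitError("R^2 undefined for constant truth")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / tss


def classify_effects(model: PGSModel, threshold: float = STRONG_THRESHOLD) -> EffectClassification:
    """null (beta = 0) / weak (0 < |beta| <= thr) / strong (|beta| > thr)."""
    absb = model.beta.abs()
    classes = pd.Series("weak", index=model.beta.index)
    classes[absb <= NULL_TOL] = "null"
    classes[absb > threshold] = "strong"
    return EffectClassification(classes=classes, threshold=threshold)


def theta_max(model: PGSModel) -> float:
    """z-score of the strongest predictor among the model's effect sizes.

    Computed on |beta| over all genes with the population (ddof=0) sd;
    NaN when the effect sizes are all equal (degenerate sd).
    """
    absb = model.beta.abs().to_numpy()
    sd = absb.std()
    if sd == 0 or not np.isfinite(sd):
        return float("nan")
    return float((absb.max() - absb.mean()) / sd)


def overfitting_assessment(
    model: PGSModel, test_sets: Sequence[Tuple[object, np.ndarray]]
) -> Dict[str, object]:
    """R^2 of the model on independent test sets; mean, sd, and per-set values."""
    r2s = [r_squared(y, predict(model, G)) for G, y in test_sets]
    return {
        "r2_test": r2s,
        "mean": float(np.mean(r2s)),
        "sd": float(np.std(r2s, ddof=1)) if len(r2s) > 1 else float("nan"),
        "r2_train": model.r2_train,
    }


def portability_experiment(
    model_std: PGSModel,
    network,
    ref,
    G: GenotypeMatrix,
    media: Sequence,
    medium_std,
    method: str = "lasso",
    threshold: float = STRONG_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Portability of a reference-medium PGS across environments.

    For each medium: recompute the population's phenotypes there, score
    the standard-medium model on them (R^2 may go negative), train that
    medium's own PGS, and count the strong predictors it shares with the
    reference model.  Returns a DataFrame with columns ``medium``,
    ``similarity``, ``r2_transfer``, ``overlap``, ``n_strong_medium``.
    """
    strong_std = set(classify_effects(model_std, threshold).strong_genes())
    rows = []
    for medium in media:
        y_m = mut_mod.population_phenotypes(network, ref, G, medium)
        sim = env_mod.similarity(network, medium, medium_std, ref=ref)
        try:
            r2_t = r_squared(y_m, predict(model_std, G))
        except DegenerateFitError:
            r2_t = float("nan")
        try:
            model_m = train_pgs(G, y_m, method=method, seed=seed, compute_cv_r2=False)
            strong_m = set(classify_effects(model_m, threshold).strong_genes())
        except DegenerateFitError:
            strong_m = set()
        rows.append(
            {
                "medium": getattr(medium, "name", ""),
                "similarity": sim,
                "r2_transfer": r2_t,
                "overlap": len(strong_std & strong_m),
                "n_strong_medium": len(strong_m),
            }
        )
    return pd.DataFrame(rows)
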