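"""Mechanistic dissection of the genotype -> growth map.

Pleiotropy (how many biomass precursors a gene's knockdown limits),
aggregate precursor contributions of predictor sets (xi), dosage-response
profiles, growth-cost matrices, and reference-bound manipulation
experiments.  These operations open the statistical black box of the
polygenic score: they locate which precursors of the biomass reaction a
predictor gene feeds, and show that predictor status is a joint property
of the functional mode (fluxes required in the medium) and the
historical reference bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import fba as fba_mod
from . import pgs as pgs_mod
from .exceptions import ConfigError, MetaPGSError
from .model import MetabolicNetwork
from .mutations import ReferenceBounds, apply_dosages, population_phenotypes
from .population import GenotypeMatrix

__all__ = [
    "PleiotropyScore",
    "pleiotropy",
    "pleiotropic_impact",
    "precursor_contribution",
    "dosage_response",
    "growth_cost_matrix",
    "manipulate_reference_bounds",
    "coupling_experiment",
]

#: Relative decrease in maximal export counting as "limited".
DECREASE_TOL = 1e-3


@dataclass
class PleiotropyScore:
    """Per-gene pleiotropy over a genotype subset.

    ``counts``: genes x individuals matrix of affected-precursor counts;
    ``affect_fraction``: genes x precursors, fraction of individuals in
    which the gene's knockdown limits that precursor.
    """

    counts: pd.DataFrame  # index genes, columns individual indices
    affect_fraction: pd.DataFrame  # index genes, columns precursor ids
    knockdown: float
    tol: float

    @property
    def mean(self) -> pd.Series:
        return self.counts.mean(axis=1)

    @property
    def sd(self) -> pd.Series:
        return self.counts.std(axis=1, ddof=0)

    def significance_threshold(self, percentile: float = 95.0) -> float:
        """Percentile of the all-gene mean-pleiotropy distribution."""
        return float(np.percentile(self.mean.to_numpy(), percentile))


def _usable_precursors(
    network: MetabolicNetwork,
    instances: Sequence[fba_mod.BoundedModel],
    medium,
) -> List[str]:
    precursors = list(network.biomass_precursors())
    usable = []
    for met in precursors:
        if any(
            fba_mod.maximize_metabolite_export(inst, met, medium) > 0
            for inst in instances
        ):
            usable.append(met)
        else:
            warnings.warn(f"precursor {met} not producible in any background; excluded")
    return usable


def pleiotropy(
    network: MetabolicNetwork,
    ref: ReferenceBounds,
    genotypes: GenotypeMatrix,
    medium,
    knockdown: float = 0.9,
    tol: float = DECREASE_TOL,
    genes: Optional[Sequence[str]] = None,
) -> PleiotropyScore:
    """Count biomass precursors whose maximal production a knockdown limits.

    For every genotype and precursor, a temporary export reaction is
    maximized with the genotype's bounds and again after reducing the
    focal gene's dosage by ``knockdown`` (default 90%); the precursor
    counts when the export optimum drops by more than ``tol`` (relative).
    Scores are averaged over the genotype subset.
    """
    genes = list(genes) if genes is not None else list(network.genes)
    n_ind = len(genotypes)
    instances = [
        apply_dosages(network, ref, genotypes.row(i)) for i in range(n_ind)
    ]
    precursors = _usable_precursors(network, instances, medium)
    counts = np.zeros((len(genes), n_ind), dtype=int)
    affected = np.zeros((len(genes), len(precursors)))
    for i in range(n_ind):
        dosages = genotypes.row(i)
        base = {
            met: fba_mod.maximize_metabolite_export(instances[i], met, medium)
            for met in precursors
        }
        for gi, gene in enumerate(genes):
            kd = dict(dosages)
            kd[gene] = kd[gene] * (1.0 - knockdown)
            inst_kd = apply_dosages(network, ref, kd)
            for pi, met in enumerate(precursors):
                if base[met] <= 0:
                    continue
                drop = fba_mod.maximize_metabolite_export(inst_kd, met, medium)
                if (base[met] - drop) / base[met] > tol:
                    counts[gi, i] += 1
                    affected[gi, pi] += 1
    return PleiotropyScore(
        counts=pd.DataFrame(counts, index=genes),
        affect_fraction=pd.DataFrame(affected / max(n_ind, 1), index=genes, columns=precursors),
        knockdown=knockdown,
        tol=tol,
    )


def pleiotropic_impact(
    pleio: PleiotropyScore,
    strong_genes: Sequence[str],
    n_null: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """z-score of how many strong predictors affect each precursor.

    The observed statistic (sum of affect fractions over the strong set)
    is compared with its null distribution over random gene sets of the
    same size drawn from the full gene repertoire.
    """
    strong = [g for g in strong_genes if g in pleio.affect_fraction.index]
    if not strong:
        raise ConfigError("strong gene set is empty or unknown")
    rng = np.random.default_rng(seed)
    A = pleio.affect_fraction.to_numpy()
    genes = list(pleio.affect_fraction.index)
    idx_strong = [genes.index(g) for g in strong]
    obs = A[idx_strong].sum(axis=0)
    null = np.empty((n_null, A.shape[1]))
    for b in range(n_null):
        pick = rng.choice(len(genes), size=len(strong), replace=False)
        null[b] = A[pick].sum(axis=0)
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mu) / sd, np.nan)
    return pd.DataFrame(
        {"observed": obs, "null_mean": mu, "null_sd": sd, "z": z},
        index=pleio.affect_fraction.columns,
    )


def _production_weights(
    network: MetabolicNetwork, solutions: Sequence[fba_mod.FluxSolution]
) -> Tuple[np.ndarray, List[str], List[int]]:
    """W[r, p] = population mean of production_{i,r,p} / consumption_{i,p}.

    xi for a gene set is then 100 * sum of W over the set's reactions:
    set-level aggregation counts each reaction once, avoiding double
    counting when several set members share a reaction.
    """
    precursors = network.biomass_precursors()
    if not precursors:
        raise MetaPGSError("biomass reaction consumes no metabolites")
    p_ids = list(precursors)
    bio_idx = network.reaction_index(network.biomass_id)
    internal_idx = [
        j for j, r in enumerate(network.reactions) if r.rxn_class == "internal"
    ]
    W = np.zeros((len(internal_idx), len(p_ids)))
    n_used = 0
    for sol in solutions:
        if not sol.feasible:
            continue
        v_bio = sol.fluxes[bio_idx]
        if v_bio <= 0:
            continue
        n_used += 1
        for rj, j in enumerate(internal_idx):
            rxn = network.reactions[j]
            v = sol.fluxes[j]
            for pi, p in enumerate(p_ids):
                coef = rxn.stoichiometry.get(p)
                if coef is None:
                    continue
                produced = coef * v
                if produced > 0:
                    W[rj, pi] += produced / (v_bio * precursors[p])
    if n_used == 0:
        raise MetaPGSError("no feasible growing solutions supplied")
    return W / n_used, p_ids, internal_idx


def precursor_contribution(
    network: MetabolicNetwork,
    solutions: Sequence[fba_mod.FluxSolution],
    gene_set: Sequence[str],
    n_randomizations: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Aggregate contribution xi of a gene set to each biomass precursor.

    xi(p) = population mean of (production of p by reactions carrying a
    set gene) / (biomass flux x biomass coefficient of p), in percent.
    Significance against ``n_randomizations`` random same-size gene sets;
    the empirical p-value uses uniform tie-breaking so it is U(0,1)
    under the null even for discrete statistics (``p_conservative``
    gives the deterministic (1+k)/(1+n) variant).
    """
    W, p_ids, internal_idx = _production_weights(network, solutions)
    rxn_genes = [network.reactions[j].genes for j in internal_idx]
    all_genes = list(network.genes)
    gene_set = list(gene_set)
    rng = np.random.default_rng(seed)

    def coverage(genes: Sequence[str]) -> np.ndarray:
        gs = set(genes)
        return np.array([bool(gr & gs) for gr in rxn_genes])

    obs = 100.0 * W[coverage(gene_set)].sum(axis=0)
    null = np.empty((n_randomizations, len(p_ids)))
    for b in range(n_randomizations):
        pick = rng.choice(all_genes, size=len(gene_set), replace=False)
        null[b] = 100.0 * W[coverage(pick)].sum(axis=0)
    n_gt = (null > obs[None, :] + 1e-12).sum(axis=0)
    n_eq = (np.abs(null - obs[None, :]) <= 1e-12).sum(axis=0)
    u = rng.random(len(p_ids))
    p_rand = (n_gt + u * (n_eq + 1)) / (n_randomizations + 1)
    p_cons = (1 + n_gt + n_eq) / (1 + n_randomizations)
    return pd.DataFrame(
        {
            "xi": obs,
            "null_mean": null.mean(axis=0),
            "p_value": p_rand,
            "p_conservative": p_cons,
        },
        index=p_ids,
    )


def dosage_response(
    network: MetabolicNetwork,
    ref: ReferenceBounds,
    gene: str,
    backgrounds: GenotypeMatrix,
    medium,
    grid: Optional[np.ndarray] = None,
    flat_range: Tuple[float, float] = (0.7, 1.0),
    flat_tol: float = 1e-6,
) -> Dict[str, object]:
    """Growth profiles as one gene's dosage sweeps [0, 1] per background.

    Returns the profile matrix (backgrounds x grid), an essentiality
    flag (zero growth at g = 0 in every background) and a per-background
    flat flag (profile constant over the population-accessible range
    ``flat_range``).
    """
    if gene not in network.genes:
        raise ConfigError(f"unknown gene {gene!r}")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    grid = np.asarray(grid, dtype=float)
    n_bg = len(backgrounds)
    profiles = np.zeros((n_bg, len(grid)))
    for i in range(n_bg):
        dosages = backgrounds.row(i)
        for j, g in enumerate(grid):
            d = dict(dosages)
            d[gene] = float(g)
            sol = fba_mod.pfba(apply_dosages(network, ref, d), medium)
            profiles[i, j] = sol.growth if sol.feasible else 0.0
    at_zero = profiles[:, grid == 0.0].ravel() if np.any(grid == 0.0) else None
    essential = bool(np.all(at_zero < 1e-9)) if at_zero is not None and len(at_zero) else None
    in_range = (grid > flat_range[0]) & (grid < flat_range[1])
    flat = (
        np.ptp(profiles[:, in_range], axis=1) < flat_tol
        if in_range.sum() >= 2
        else np.full(n_bg, False)
    )
    return {"grid": grid, "profiles": profiles, "essential": essential, "flat": flat}


def growth_cost_matrix(
    network: MetabolicNetwork,
    ref: ReferenceBounds,
    genotypes: GenotypeMatrix,
    medium,
    knockdown: float = 0.9,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Relative growth cost of per-gene knockdowns, genes x individuals.

    cost = (growth_baseline - growth_knockdown) / growth_baseline;
    NaN where the baseline does not grow.
    """
    genes = list(genes) if genes is not None else list(network.genes)
    n_ind = len(genotypes)
    costs = np.full((len(genes), n_ind), np.nan)
    for i in range(n_ind):
        dosages = genotypes.row(i)
        base = fba_mod.pfba(apply_dosages(network, ref, dosages), medium).growth
        if base <= 0:
            continue
        for gi, gene in enumerate(genes):
            kd = dict(dosages)
            kd[gene] = kd[gene] * (1.0 - knockdown)
            g_kd = fba_mod.pfba(apply_dosages(network, ref, kd), medium).growth
            costs[gi, i] = (base - g_kd) / base
    return pd.DataFrame(costs, index=genes)


def manipulate_reference_bounds(
    ref: ReferenceBounds,
    edits: Mapping[str, Union[float, Tuple[str, object]]],
    network: Optional[MetabolicNetwork] = None,
) -> ReferenceBounds:
    """Return a copy of the reference bounds with per-reaction edits.

    Edit values: a bare float scales both bounds; ``("scale", f)`` is
    explicit; ``("set", (lb, ub))`` assigns absolute bounds.  Edits on
    exempt reactions (or reactions absent from the reference set) raise.
    """
    out = ref.copy()
    for rxn_id, edit in edits.items():
        if rxn_id not in out.upper:
            if network is not None and rxn_id in {r.id for r in network.reactions}:
                raise ConfigError(f"{rxn_id!r} is exempt; its bounds cannot be edited")
            raise ConfigError(f"{rxn_id!r} has no reference bounds")
        if isinstance(edit, tuple):
            kind, value = edit
            if kind == "scale":
                out.upper[rxn_id] *= float(value)
                out.lower[rxn_id] = out.lower.get(rxn_id, 0.0) * float(value)
            elif kind == "set":
                lb, ub = value
                out.lower[rxn_id], out.upper[rxn_id] = float(lb), float(ub)
            else:
                raise ConfigError(f"unknown edit kind {kind!r}")
        else:
            out.upper[rxn_id] *= float(edit)
            out.lower[rxn_id] = out.lower.get(rxn_id, 0.0) * float(edit)
    out.provenance = dict(out.provenance)
    out.provenance.setdefault("edits", []).append({str(k): repr(v) for k, v in edits.items()})
    return out


def coupling_experiment(
    network: MetabolicNetwork,
    ref: ReferenceBounds,
    G: GenotypeMatrix,
    medium,
    n_iterations: int,
    group_size_range: Tuple[int, int] = (10, 60),
    raise_factor: float = 10.0,
    lower_factor: float = 0.5,
    seed: int = 0,
    method: str = "lasso",
    threshold: float = pgs_mod.STRONG_THRESHOLD,
) -> pd.DataFrame:
    """Couple/uncouple random reaction groups and retrain the PGS.

    Per iteration a random group of internal reactions (size drawn from
    ``group_size_range``, capped at availability) has its reference
    bounds scaled up ("uncouple": variation turns cryptic) or down
    ("couple": new reactions become limiting); phenotypes are
    regenerated and a fresh PGS trained.  The output table (one row per
    iteration plus the unmanipulated baseline) supports the
    predictor-count vs R^2 relation.
    """
    rng = np.random.default_rng(seed)
    internal_ids = sorted(ref.upper)
    rows = []

    def record(tag: str, the_ref: ReferenceBounds, group_size: int) -> None:
        y = population_phenotypes(network, ref=the_ref, G=G, medium=medium)
        try:
            model = pgs_mod.train_pgs(
                G, y, method=method, seed=seed, compute_cv_r2=False
            )
            r2 = model.r2_train
            n_strong = len(pgs_mod.classify_effects(model, threshold).strong_genes())
        except pgs_mod.DegenerateFitError:
            r2, n_strong = float("nan"), 0
        rows.append(
            {"manipulation": tag, "group_size": group_size, "n_strong": n_strong, "r2": r2}
        )

    record("baseline", ref, 0)
    lo, hi = group_size_range
    for _ in range(n_iterations):
        size = min(int(rng.integers(lo, hi + 1)), len(internal_ids))
        group = rng.choice(internal_ids, size=size, replace=False)
        couple = bool(rng.integers(2))
        factor = lower_factor if couple else raise_factor
        edited = manipulate_reference_bounds(ref, {r: factor for r in group}, network)
        record("couple" if couple else "uncouple", edited, size)
    return pd.DataFrame(rows)
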