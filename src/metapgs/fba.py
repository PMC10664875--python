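"""Flux balance analysis (FBA) and parsimonious FBA on scipy's HiGHS solver.

Phenotypes throughout the package are computed by pFBA: a first LP
maximizes the biomass flux (the growth rate, 1/h) subject to the
steady-state constraint S v = 0 and the instance's flux bounds; a second
LP fixes growth at that optimum and minimizes the total absolute flux
via the standard forward/reverse flux splitting.  pFBA picks a canonical
solution among degenerate FBA optima; plain FBA is retained for
objectives other than growth (e.g. maximal metabolite export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .exceptions import MetaPGSError
from .model import MetabolicNetwork

__all__ = [
    "BoundedModel",
    "FluxSolution",
    "as_instance",
    "reference_instance",
    "fba",
    "pfba",
    "maximize_metabolite_export",
    "unused_flux_fraction",
    "population_flux_stats",
]

#: Solver feasibility tolerance recorded in solution metadata.
FEASIBILITY_TOL = 1e-9
#: Relative slack when pinning growth at the FBA optimum in pFBA stage 2.
GROWTH_PIN_RTOL = 1e-9


@dataclass
class BoundedModel:
    """A network together with a working set of flux bounds.

    Produced by :func:`metapgs.mutations.apply_dosages` (dosage-scaled
    reference bounds) or by the helpers below.  The bound arrays are
    aligned with ``network.reactions``.
    """

    network: MetabolicNetwork
    lb: np.ndarray
    ub: np.ndarray

    def copy(self) -> "BoundedModel":
        return BoundedModel(self.network, self.lb.copy(), self.ub.copy())


Instance = Union[MetabolicNetwork, BoundedModel]


def as_instance(instance: Instance) -> BoundedModel:
    """Coerce a network (with its native bounds) or BoundedModel to the latter."""
    if isinstance(instance, BoundedModel):
        return instance
    lb, ub = instance.default_bounds()
    return BoundedModel(instance, lb, ub)


def reference_instance(network: MetabolicNetwork, ref) -> BoundedModel:
    """Instance with wild-type reference bounds (all dosages = 1).

    ``ref`` is duck-typed: any object with ``lower``/``upper`` mappings
    reaction id -> flux (see :class:`metapgs.mutations.ReferenceBounds`).
    """
    lb, ub = network.default_bounds()
    for i, rxn in enumerate(network.reactions):
        if rxn.id in ref.upper:
            lb[i] = ref.lower.get(rxn.id, 0.0)
            ub[i] = ref.upper[rxn.id]
    return BoundedModel(network, lb, ub)


@dataclass
class FluxSolution:
    """One flux distribution: per-reaction fluxes, growth, and status."""

    reaction_ids: List[str]
    fluxes: np.ndarray
    growth: float
    status: str  # "optimal" | "infeasible"
    total_abs_flux: float
    meta: Dict[str, float] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(rxn_id)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.fluxes, index=self.reaction_ids, name="flux")

    def to_tsv(self, path) -> None:
        self.as_series().rename_axis("reaction_id").to_csv(path, sep="\t")


def _medium_bounds(bm: BoundedModel, medium) -> Tuple[np.ndarray, np.ndarray]:
    """Apply a medium: every exchange import bound is overwritten.

    Imports (negative flux through an exchange) are capped at the medium's
    rate, closed when the exchange is absent; exports stay open at the
    instance's upper bound.
    """
    lb, ub = bm.lb.copy(), bm.ub.copy()
    if medium is None:
        return lb, ub
    imports = medium.imports
    for i, rxn in enumerate(bm.network.reactions):
        if rxn.rxn_class == "exchange":
            lb[i] = -float(imports.get(rxn.id, 0.0))
            ub[i] = max(ub[i], 0.0)
    return lb, ub


def _solve_lp(c, A_eq, b_eq, lb, ub):
    bounds = np.column_stack([lb, ub])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    return res


def _infeasible(network: MetabolicNetwork) -> FluxSolution:
    n = network.n_reactions
    return FluxSolution(
        [r.id for r in network.reactions],
        np.zeros(n),
        growth=0.0,
        status="infeasible",
        total_abs_flux=0.0,
        meta={"feasibility_tol": FEASIBILITY_TOL},
    )


def fba(instance: Instance, medium=None) -> FluxSolution:
    """Maximize biomass flux subject to S v = 0 and the instance bounds.

    Infeasible problems return a zero-growth solution flagged
    ``status="infeasible"`` (distinct from a feasible optimum of zero).
    """
    bm = as_instance(instance)
    net = bm.network
    lb, ub = _medium_bounds(bm, medium)
    S = net.stoichiometric_matrix()
    c = np.zeros(net.n_reactions)
    c[net.reaction_index(net.biomass_id)] = -1.0
    res = _solve_lp(c, S, np.zeros(S.shape[0]), lb, ub)
    if not res.success:
        return _infeasible(net)
    v = res.x
    return FluxSolution(
        [r.id for r in net.reactions],
        v,
        growth=float(v[net.reaction_index(net.biomass_id)]),
        status="optimal",
        total_abs_flux=float(np.abs(v).sum()),
        meta={"feasibility_tol": FEASIBILITY_TOL},
    )


def pfba(instance: Instance, medium=None) -> FluxSolution:
    """Parsimonious FBA: fix growth at the FBA optimum, minimize sum |v|."""
    bm = as_instance(instance)
    net = bm.network
    stage1 = fba(bm, medium)
    if not stage1.feasible:
        return stage1
    growth = stage1.growth
    lb, ub = _medium_bounds(bm, medium)
    bio = net.reaction_index(net.biomass_id)
    # pin growth with a tiny downward slack so stage 2 stays feasible
    lb[bio] = growth - abs(growth) * GROWTH_PIN_RTOL - 1e-12
    ub[bio] = min(ub[bio], growth + abs(growth) * GROWTH_PIN_RTOL + 1e-12)

    n = net.n_reactions
    S = net.stoichiometric_matrix()
    A = sparse.hstack([S, -S]).tocsr()
    # split v = v+ - v- with nonnegative parts; handle strictly signed bounds
    lb_pos = np.maximum(lb, 0.0)
    ub_pos = np.maximum(ub, 0.0)
    lb_neg = np.maximum(-ub, 0.0)
    ub_neg = np.maximum(-lb, 0.0)
    c = np.ones(2 * n)
    res = _solve_lp(
        c,
        A,
        np.zeros(S.shape[0]),
        np.concatenate([lb_pos, lb_neg]),
        np.concatenate([ub_pos, ub_neg]),
    )
    if not res.success:  # numerically pinched pin; fall back to the FBA solution
        return stage1
    v = res.x[:n] - res.x[n:]
    # report the stage-1 optimum as the growth phenotype; the stage-2 flux
    # vector's biomass entry may sit at the pin's lower edge (<= 1e-8 off)
    return FluxSolution(
        [r.id for r in net.reactions],
        v,
        growth=growth,
        status="optimal",
        total_abs_flux=float(np.abs(v).sum()),
        meta={"feasibility_tol": FEASIBILITY_TOL, "stage2_growth": float(v[bio])},
    )


def maximize_metabolite_export(instance: Instance, met_id: str, medium=None) -> float:
    """Maximal producibility of a metabolite: add a temporary export and
    maximize its flux (plain FBA; growth is left free).

    Used by the pleiotropy machinery on biomass precursors.
    """
    bm = as_instance(instance)
    net = bm.network
    lb, ub = _medium_bounds(bm, medium)
    S = net.stoichiometric_matrix().tocsc()
    met_row = net.metabolites.index(net.metabolite(met_id))
    export_col = sparse.csc_matrix(
        ([-1.0], ([met_row], [0])), shape=(S.shape[0], 1)
    )
    A = sparse.hstack([S, export_col]).tocsr()
    n = net.n_reactions
    c = np.zeros(n + 1)
    c[n] = -1.0
    res = _solve_lp(
        c,
        A,
        np.zeros(S.shape[0]),
        np.concatenate([lb, [0.0]]),
        np.concatenate([ub, [np.inf]]),
    )
    if not res.success:
        return 0.0
    return float(res.x[n])


def unused_flux_fraction(sol: FluxSolution, zero_tol: float = 1e-6) -> float:
    """Fraction of reactions carrying |flux| below ``zero_tol``."""
    if not sol.feasible:
        raise MetaPGSError("unused_flux_fraction requires a feasible solution")
    return float(np.mean(np.abs(sol.fluxes) < zero_tol))


def population_flux_stats(solutions: Sequence[FluxSolution]) -> Dict[str, object]:
    """Population summaries: the 'mean metabolism', per-reaction CV, and each
    individual's correlation with the mean metabolism.

    Returns a dict with keys ``mean_flux`` (Series), ``cv`` (Series; NaN
    where the mean flux is 0) and ``correlation_with_mean`` (ndarray, one
    entry per individual).
    """
    if len(solutions) < 2:
        raise MetaPGSError("need at least two solutions")
    ids = solutions[0].reaction_ids
    for sol in solutions:
        if sol.reaction_ids != ids:
            raise MetaPGSError("solutions cover different reaction sets")
    V = np.vstack([sol.fluxes for sol in solutions])
    mean = V.mean(axis=0)
    sd = V.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0.0, sd / np.abs(mean), np.nan)
    mean_centered = mean - mean.mean()
    denom_m = np.linalg.norm(mean_centered)
    corr = np.full(len(solutions), np.nan)
    for i, row in enumerate(V):
        rc = row - row.mean()
        denom = np.linalg.norm(rc) * denom_m
        if denom > 0:
            corr[i] = float(rc @ mean_centered / denom)
    return {
        "mean_flux": pd.Series(mean, index=ids, name="mean_flux"),
        "cv": pd.Series(cv, index=ids, name="cv"),
        "correlation_with_mean": corr,
    }
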