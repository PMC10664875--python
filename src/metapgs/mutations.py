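"""Quantitative mutations: gene dosages -> per-reaction flux bounds.

The genotype-to-phenotype map rests on two steps:

1. *Reference ("wild-type") bounds.*  An ensemble of optimal solutions —
   pairs of pFBA solutions (native bounds / randomly rebounded internals)
   across random media — stands in for the metabolism's evolutionary
   history.  Each internal reaction's reference upper (and, if
   reversible, lower) bound is the extreme flux observed across the
   ensemble.  Exchange, biomass and ATP-maintenance reactions keep their
   model bounds throughout.

2. *Dosage scaling.*  A genotype's relative dosages are pushed through
   each reaction's gene-reaction rule (AND -> min, OR -> clipped sum),
   giving a multiplier delta_r in [0, 1]; the mutant bounds are
   delta_r * reference bounds, respecting reversibility.

Growth is therefore nondecreasing in every dosage coordinate: reducing a
dosage can only tighten bounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fba as fba_mod
from .exceptions import EnsembleError, MetaPGSError
from .fba import BoundedModel
from .grr import evaluate_grr
from .model import MetabolicNetwork
from .population import GenotypeMatrix

__all__ = [
    "ReferenceBounds",
    "evaluate_grr",
    "grr_multipliers",
    "compute_reference_bounds",
    "apply_dosages",
    "population_phenotypes",
]


@dataclass
class ReferenceBounds:
    """Wild-type flux limits per internal reaction, with provenance.

    Only non-exempt (internal) reactions appear in ``lower``/``upper``;
    exempt classes implicitly keep their model bounds.
    """

    lower: Dict[str, float]
    upper: Dict[str, float]
    provenance: Dict[str, object] = field(default_factory=dict)

    def copy(self) -> "ReferenceBounds":
        return ReferenceBounds(dict(self.lower), dict(self.upper), dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.upper)
        return pd.DataFrame(
            {
                "reaction_id": ids,
                "lb": [self.lower.get(r, 0.0) for r in ids],
                "ub": [self.upper[r] for r in ids],
            }
        )

    def to_tsv(self, path, provenance_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump(self.provenance, fh, indent=1, default=str)

    @classmethod
    def from_tsv(cls, path, provenance_path=None) -> "ReferenceBounds":
        df = pd.read_csv(path, sep="\t")
        prov: Dict[str, object] = {}
        if provenance_path is not None:
            with open(provenance_path) as fh:
                prov = json.load(fh)
        return cls(
            dict(zip(df["reaction_id"], df["lb"].astype(float))),
            dict(zip(df["reaction_id"], df["ub"].astype(float))),
            prov,
        )


def grr_multipliers(
    network: MetabolicNetwork, dosages: Mapping[str, float]
) -> Dict[str, float]:
    """delta_r for every internal reaction of the network."""
    return {
        r.id: evaluate_grr(r.grr, dosages)
        for r in network.reactions
        if r.rxn_class == "internal"
    }


def _random_internal_bounds(
    network: MetabolicNetwork,
    bound_range: Tuple[float, float],
    rng: np.random.Generator,
) -> BoundedModel:
    """One 'random genetic background': internal upper bounds drawn uniformly
    from ``bound_range``; reversible internals get the negated draw as lower
    bound; exempt classes keep model bounds."""
    lb, ub = network.default_bounds()
    lo, hi = bound_range
    for i, rxn in enumerate(network.reactions):
        if rxn.rxn_class != "internal":
            continue
        draw = rng.uniform(lo, hi)
        ub[i] = draw
        lb[i] = -draw if rxn.reversible else 0.0
    return BoundedModel(network, lb, ub)


def compute_reference_bounds(
    network: MetabolicNetwork,
    n_media: int,
    bound_range: Tuple[float, float] = (0.0, 100.0),
    rng_seed: int = 0,
    media: Optional[Sequence] = None,
    env_config=None,
) -> ReferenceBounds:
    """Derive wild-type reference bounds from an evolutionary-history ensemble.

    For each of ``n_media`` random media two pFBA problems are solved —
    the model with its native bounds and a copy whose internal bounds are
    resampled uniformly from ``bound_range`` — yielding up to
    ``2 * n_media`` flux vectors.  Per internal reaction the reference
    upper bound is the maximum flux observed (floored at 0) and the lower
    bound the minimum (capped at 0) when reversible, else 0.  A reaction
    never active in any solution ends up permanently closed.

    ``media`` may supply an explicit medium list (e.g. for toy networks);
    otherwise media are generated by :func:`metapgs.environments.random_media`
    with richness assessed on the model's native bounds.
    """
    if n_media < 1:
        raise MetaPGSError("n_media must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if media is None:
        # imported here: environments depends on fba, and reference bounds
        # need media — the ensemble is the one place the two meet
        from . import environments as env_mod

        if env_config is None:
            env_config = env_mod.EnvironmentConfig(
                n=n_media, seed=int(rng.integers(2**31))
            )
        media = env_mod.random_media(network, env_config, ref=None)
    media = list(media)[:n_media]

    internals = [r for r in network.reactions if r.rxn_class == "internal"]
    n_solved = 0
    n_skipped = 0
    upper = {r.id: 0.0 for r in internals}
    lower = {r.id: 0.0 for r in internals}
    for medium in media:
        plain = fba_mod.pfba(network, medium)
        rebounded = fba_mod.pfba(
            _random_internal_bounds(network, bound_range, rng), medium
        )
        for sol in (plain, rebounded):
            if not sol.feasible:
                n_skipped += 1
                warnings.warn(f"infeasible ensemble sample in medium {medium.name!r}")
                continue
            n_solved += 1
            flux = sol.as_series()
            for rxn in internals:
                v = float(flux[rxn.id])
                if v > upper[rxn.id]:
                    upper[rxn.id] = v
                if rxn.reversible and v < lower[rxn.id]:
                    lower[rxn.id] = v
    if n_solved == 0:
        raise EnsembleError("every ensemble sample was infeasible")
    return ReferenceBounds(
        lower,
        upper,
        provenance={
            "n_media": len(media),
            "n_solutions": n_solved,
            "n_skipped": n_skipped,
            "bound_range": list(bound_range),
            "rng_seed": rng_seed,
        },
    )


def apply_dosages(
    network: MetabolicNetwork,
    ref: ReferenceBounds,
    dosages: Mapping[str, float],
) -> BoundedModel:
    """Scale reference bounds by the genotype's GRR multipliers.

    Internal reactions get ``ub = delta_r * f_ub`` and, when reversible,
    ``lb = delta_r * f_lb`` (else 0); exempt classes keep model bounds.
    """
    lb, ub = network.default_bounds()
    for i, rxn in enumerate(network.reactions):
        if rxn.rxn_class != "internal":
            continue
        try:
            f_ub = ref.upper[rxn.id]
        except KeyError:
            raise MetaPGSError(
                f"reference bounds do not cover reaction {rxn.id!r}"
            ) from None
        delta = evaluate_grr(rxn.grr, dosages)
        ub[i] = delta * f_ub
        lb[i] = delta * ref.lower.get(rxn.id, 0.0) if rxn.reversible else 0.0
    return BoundedModel(network, lb, ub)


def population_phenotypes(
    network: MetabolicNetwork,
    ref: ReferenceBounds,
    G: GenotypeMatrix,
    medium,
    parsimonious: bool = True,
    return_solutions: bool = False,
):
    """Growth rate of every individual in a medium (pFBA by default).

    Returns an array of growth rates, or ``(growth, solutions)`` when
    ``return_solutions`` is set.
    """
    solver = fba_mod.pfba if parsimonious else fba_mod.fba
    growth = np.zeros(len(G))
    solutions = []
    for i, dosages in enumerate(G.iter_rows()):
        sol = solver(apply_dosages(network, ref, dosages), medium)
        growth[i] = sol.growth if sol.feasible else 0.0
        if return_solutions:
            solutions.append(sol)
    if return_solutions:
        return growth, solutions
    return growth
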