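"""Toy metabolic scenarios with closed-form growth functions.

These fixtures reproduce, in miniature, the structural mechanisms that
shape growth prediction on genome-scale models: isozyme (OR) and complex
(AND) gene-reaction rules, reversible steps, exempt reaction classes,
reference-bound slack ("cryptic" variation that never limits flux), and
multi-precursor biomass reactions with shared upstream enzymes
(pleiotropy).  Every scenario carries an analytic min-form growth
function that must agree with the LP solution to high precision, so each
pipeline stage can be tested against a hand-checkable oracle with no
model download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import fba as fba_mod
from .environments import Medium
from .exceptions import ConfigError, FixtureIntegrityError
from .grr import NO_GENE, AndRule, GeneRef, OrRule
from .model import MetabolicNetwork, Metabolite, Reaction
from .mutations import ReferenceBounds, apply_dosages
from .population import GenotypeMatrix, PopulationConfig, sample_population

__all__ = ["ToyScenario", "toy_chain", "toy3", "toy_branched", "scenario_dataset"]

_BIG = 1000.0


@dataclass
class ToyScenario:
    """A toy network bundled with reference bounds, medium, and ground truth."""

    name: str
    network: MetabolicNetwork
    ref: ReferenceBounds
    medium: Medium
    genes: List[str]
    analytic_growth: Callable[..., np.ndarray]
    planted: List[str] = field(default_factory=list)
    meta: Dict[str, object] = field(default_factory=dict)

    def lp_growth(self, dosages: Mapping[str, float], medium: Optional[Medium] = None) -> float:
        sol = fba_mod.pfba(
            apply_dosages(self.network, self.ref, dosages),
            medium if medium is not None else self.medium,
        )
        return sol.growth if sol.feasible else 0.0


def _as_matrix(G, genes: Sequence[str]) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        if list(G.genes) != list(genes):
            raise ConfigError("genotype matrix gene order does not match scenario")
        return G.values
    arr = np.atleast_2d(np.asarray(G, dtype=float))
    if arr.shape[1] != len(genes):
        raise ConfigError("dosage array width does not match scenario genes")
    return arr


def _slack_for(position: int, ref_slack) -> float:
    if ref_slack is None:
        return 1.0
    if isinstance(ref_slack, Mapping):
        return float(ref_slack.get(position, 1.0))
    return float(ref_slack)


def toy_chain(
    length: int = 2,
    isozyme_positions: Sequence[int] = (),
    complex_positions: Sequence[int] = (),
    ref_slack: Union[None, float, Mapping[int, float]] = None,
    uptake: float = 10.0,
    n_substrates: int = 1,
    reversible_positions: Sequence[int] = (),
    name: str = "toy-chain",
) -> ToyScenario:
    """Linear pathway nutrient -> ... -> biomass, one enzyme per step.

    ``length`` counts enzymatic steps (positions 1..length).  Isozyme
    positions carry an OR over two genes, complex positions an AND;
    genes are numbered sequentially (g1, g2, ...) so the default
    ``toy_chain(2, isozyme_positions=(2,))`` is the TOY3 network with
    growth ``uptake * min(g1, min(1, g2 + g3))``.  ``ref_slack`` sets
    per-position headroom factors: a reference bound of
    ``slack * uptake``; positions with slack > 1 carry cryptic variation
    at typical population dosages.  With ``n_substrates > 1`` the first
    metabolite is fed by parallel substrate-uptake enzymes (genes u1,
    u2, ...), and the capacity into the chain is the sum of the
    per-substrate minima.
    """
    if length < 1:
        raise ConfigError("chain length must be >= 1")
    overlap = set(isozyme_positions) & set(complex_positions)
    if overlap:
        raise ConfigError(f"positions {overlap} are both isozyme and complex")

    mets: List[Metabolite] = []
    reactions: List[Reaction] = []
    genes: List[str] = []
    sub_ex_ids: List[str] = []

    if n_substrates == 1:
        mets.append(Metabolite("nut_e", "nutrient", "e", "C6H12O6"))
        reactions.append(
            Reaction("EX_nut", {"nut_e": -1.0}, 0.0, _BIG, rxn_class="exchange")
        )
        sub_ex_ids.append("EX_nut")
        chain_input = "nut_e"
    else:
        mets.append(Metabolite("m0_c", "hub", "c", "C6H12O6"))
        for j in range(1, n_substrates + 1):
            sid = f"sub{j}_e"
            mets.append(Metabolite(sid, f"substrate {j}", "e", "C6H12O6"))
            ex_id = f"EX_sub{j}"
            reactions.append(Reaction(ex_id, {sid: -1.0}, 0.0, _BIG, rxn_class="exchange"))
            sub_ex_ids.append(ex_id)
            gene = f"u{j}"
            genes.append(gene)
            reactions.append(
                Reaction(f"U{j}", {sid: -1.0, "m0_c": 1.0}, 0.0, _BIG, grr=GeneRef(gene))
            )
        chain_input = "m0_c"

    structure: List[Tuple[str, List[str]]] = []  # (kind, gene ids) per position
    counter = 1
    for k in range(1, length + 1):
        if k in isozyme_positions or k in complex_positions:
            gs = [f"g{counter}", f"g{counter + 1}"]
            counter += 2
            kind = "or" if k in isozyme_positions else "and"
        else:
            gs = [f"g{counter}"]
            counter += 1
            kind = "single"
        genes.extend(gs)
        structure.append((kind, gs))
        if kind == "or":
            rule = OrRule((GeneRef(gs[0]), GeneRef(gs[1])))
        elif kind == "and":
            rule = AndRule((GeneRef(gs[0]), GeneRef(gs[1])))
        else:
            rule = GeneRef(gs[0])
        mets.append(Metabolite(f"m{k}_c", f"intermediate {k}", "c", "C6H12O6"))
        lower = -_BIG if k in reversible_positions else 0.0
        reactions.append(
            Reaction(
                f"R{k}",
                {(chain_input if k == 1 else f"m{k - 1}_c"): -1.0, f"m{k}_c": 1.0},
                lower,
                _BIG,
                grr=rule,
            )
        )
    reactions.append(
        Reaction("BIOMASS", {f"m{length}_c": -1.0}, 0.0, _BIG, rxn_class="biomass")
    )

    network = MetabolicNetwork(mets, reactions, genes=genes, id=name)

    ref_lower: Dict[str, float] = {}
    ref_upper: Dict[str, float] = {}
    slack_by_rxn: Dict[str, float] = {}
    if n_substrates > 1:
        for j in range(1, n_substrates + 1):
            ref_upper[f"U{j}"] = uptake * _slack_for(-j, ref_slack)
            ref_lower[f"U{j}"] = 0.0
    for k in range(1, length + 1):
        s = _slack_for(k, ref_slack)
        slack_by_rxn[f"R{k}"] = s
        ref_upper[f"R{k}"] = uptake * s
        ref_lower[f"R{k}"] = -uptake * s if k in reversible_positions else 0.0
    ref = ReferenceBounds(ref_lower, ref_upper, {"constructed": "toy_chain"})

    medium = Medium({ex: uptake for ex in sub_ex_ids}, name=f"{name}-standard")

    gene_index = {g: i for i, g in enumerate(genes)}
    min_slack = min(
        [_slack_for(k, ref_slack) for k in range(1, length + 1)]
        + ([1.0] if n_substrates == 1 else [])
    )
    planted = [
        g
        for k, (kind, gs) in enumerate(structure, start=1)
        if _slack_for(k, ref_slack) == min_slack and min_slack <= 1.0
        for g in gs
    ]

    def analytic_growth(G, medium: Optional[Medium] = None) -> np.ndarray:
        med = medium if medium is not None else Medium({ex: uptake for ex in sub_ex_ids})
        M = _as_matrix(G, genes)
        if n_substrates == 1:
            capacity = np.full(M.shape[0], med.imports.get(sub_ex_ids[0], 0.0))
        else:
            capacity = np.zeros(M.shape[0])
            for j in range(1, n_substrates + 1):
                u_j = med.imports.get(f"EX_sub{j}", 0.0)
                dos = M[:, gene_index[f"u{j}"]]
                capacity += np.minimum(u_j, uptake * _slack_for(-j, ref_slack) * dos)
        growth = capacity
        for k, (kind, gs) in enumerate(structure, start=1):
            cols = M[:, [gene_index[g] for g in gs]]
            if kind == "or":
                delta = np.minimum(1.0, cols.sum(axis=1))
            elif kind == "and":
                delta = cols.min(axis=1)
            else:
                delta = cols[:, 0]
            growth = np.minimum(growth, uptake * slack_by_rxn[f"R{k}"] * delta)
        return growth

    return ToyScenario(
        name=name,
        network=network,
        ref=ref,
        medium=medium,
        genes=genes,
        analytic_growth=analytic_growth,
        planted=planted,
        meta={"uptake": uptake, "length": length, "structure": structure},
    )


def toy3(uptake: float = 10.0) -> ToyScenario:
    """The canonical 4-reaction, 3-gene chain: EX -> R1(g1) -> R2(g2 or g3) -> biomass.

    Growth is ``uptake * min(g1, min(1, g2 + g3))``.
    """
    return toy_chain(length=2, isozyme_positions=(2,), uptake=uptake, name="TOY3")


def toy_branched(
    n_precursors: int = 2,
    shared_upstream: bool = True,
    coefs: Optional[Sequence[float]] = None,
    slack_upstream: float = 2.0,
    slack_branches: Union[float, Sequence[float]] = 1.0,
    uptake: float = 10.0,
    name: str = "toy-branched",
) -> ToyScenario:
    """Multi-precursor biomass fed from a hub, optionally via a shared enzyme.

    Biomass consumes ``n_precursors`` metabolites with distinct
    stoichiometric coefficients (default 1, 2, ...).  The shared
    upstream enzyme (gene ``g0``) makes every precursor's producibility
    depend on one gene (pleiotropy = n_precursors); branch gene ``b{i}``
    is the sole producer of precursor ``p{i}``.  Branch reference bounds
    are ``slack * c_i * y_wt`` with ``y_wt = uptake / sum(c)``, so
    branches with slack 1 are the planted growth predictors.
    """
    if n_precursors < 2:
        raise ConfigError("need at least 2 precursors")
    c = np.asarray(coefs if coefs is not None else range(1, n_precursors + 1), float)
    if len(c) != n_precursors or np.any(c <= 0):
        raise ConfigError("coefs must give one positive value per precursor")
    slacks = (
        np.full(n_precursors, float(slack_branches))
        if np.isscalar(slack_branches)
        else np.asarray(slack_branches, float)
    )
    y_wt = uptake / c.sum()

    mets = [
        Metabolite("sub_e", "substrate", "e", "C6H12O6"),
        Metabolite("hub_c", "hub", "c", "C6H12O6"),
    ]
    reactions = [
        Reaction("EX_sub", {"sub_e": -1.0}, 0.0, _BIG, rxn_class="exchange"),
        Reaction(
            "R0",
            {"sub_e": -1.0, "hub_c": 1.0},
            0.0,
            _BIG,
            grr=GeneRef("g0") if shared_upstream else NO_GENE,
        ),
    ]
    genes = ["g0"] if shared_upstream else []
    biomass_stoich: Dict[str, float] = {}
    ref_upper: Dict[str, float] = {"R0": uptake * slack_upstream}
    ref_lower: Dict[str, float] = {"R0": 0.0}
    for i in range(1, n_precursors + 1):
        mets.append(Metabolite(f"p{i}_c", f"precursor {i}", "c", "C6H12O6"))
        gene = f"b{i}"
        genes.append(gene)
        reactions.append(
            Reaction(f"B{i}", {"hub_c": -1.0, f"p{i}_c": 1.0}, 0.0, _BIG, grr=GeneRef(gene))
        )
        biomass_stoich[f"p{i}_c"] = -float(c[i - 1])
        ref_upper[f"B{i}"] = float(slacks[i - 1] * c[i - 1] * y_wt)
        ref_lower[f"B{i}"] = 0.0
    reactions.append(Reaction("BIOMASS", biomass_stoich, 0.0, _BIG, rxn_class="biomass"))

    network = MetabolicNetwork(mets, reactions, genes=genes, id=name)
    ref = ReferenceBounds(ref_lower, ref_upper, {"constructed": "toy_branched"})
    medium = Medium({"EX_sub": uptake}, name=f"{name}-standard")
    gene_index = {g: i for i, g in enumerate(genes)}

    def analytic_growth(G, medium: Optional[Medium] = None) -> np.ndarray:
        med = medium if medium is not None else Medium({"EX_sub": uptake})
        M = _as_matrix(G, genes)
        u = med.imports.get("EX_sub", 0.0)
        delta0 = M[:, gene_index["g0"]] if shared_upstream else np.ones(M.shape[0])
        upstream = np.minimum(u, uptake * slack_upstream * delta0)
        growth = upstream / c.sum()
        for i in range(1, n_precursors + 1):
            cap = ref.upper[f"B{i}"] * M[:, gene_index[f"b{i}"]] / c[i - 1]
            growth = np.minimum(growth, cap)
        return growth

    planted = [f"b{i}" for i in range(1, n_precursors + 1) if slacks[i - 1] <= 1.0]
    if shared_upstream and slack_upstream <= 1.0:
        planted.insert(0, "g0")
    return ToyScenario(
        name=name,
        network=network,
        ref=ref,
        medium=medium,
        genes=genes,
        analytic_growth=analytic_growth,
        planted=planted,
        meta={"uptake": uptake, "coefs": c.tolist(), "shared_upstream": shared_upstream},
    )


def scenario_dataset(
    scenario: ToyScenario,
    n_individuals: int,
    sigma: float = 0.1,
    seed: Optional[int] = None,
    family: str = "normal",
    k: Optional[float] = None,
    lp_check: Union[int, str] = "all",
    tol: float = 1e-8,
) -> Tuple[GenotypeMatrix, np.ndarray]:
    """Sample a population on a scenario and return (genotypes, growth).

    Growth is evaluated with the scenario's closed form and verified
    against pFBA on ``lp_check`` individuals (``"all"`` or a count;
    checked rows are spread evenly); disagreement beyond ``tol`` raises
    :class:`FixtureIntegrityError`.
    """
    config = PopulationConfig(n=n_individuals, family=family, sigma=sigma, k=k, seed=seed)
    G = sample_population(config, scenario.genes)
    y = scenario.analytic_growth(G)
    n_check = n_individuals if lp_check == "all" else int(lp_check)
    idx = np.unique(np.linspace(0, n_individuals - 1, max(0, n_check)).astype(int))
    worst = 0.0
    for i in idx:
        lp = scenario.lp_growth(G.row(int(i)))
        worst = max(worst, abs(lp - y[i]))
    if worst > tol:
        raise FixtureIntegrityError(
            f"analytic vs LP growth disagree by {worst:.3e} (> {tol:.1e}) "
            f"on scenario {scenario.name!r}"
        )
    return G, y
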