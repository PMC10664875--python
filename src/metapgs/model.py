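"""Genome-scale metabolic network container and model I/O.

The package works on a lightweight immutable-ish network representation:
stoichiometry, per-reaction flux bounds, parsed gene-reaction-rule trees,
subsystem annotations, and a four-way reaction classification
(``internal`` / ``exchange`` / ``biomass`` / ``atp-maintenance``).  The
last three classes are exempt from dosage-derived bound modifications:
quantitative mutations act on internal (enzymatic) reactions only.

File I/O (BiGG JSON and SBML with the fbc extension) is delegated to
cobrapy; this module converts between ``cobra.Model`` and
:class:`MetabolicNetwork`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from . import grr as grr_mod
from .exceptions import ModelFormatError, ModelValidationError
from .grr import GRRTree, NO_GENE

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "load_model",
    "save_json",
    "from_cobra",
    "to_cobra",
    "gene_subsystem_map",
    "REACTION_CLASSES",
    "EXEMPT_CLASSES",
]

REACTION_CLASSES = ("internal", "exchange", "biomass", "atp-maintenance")
#: Classes whose bounds are never rescaled by gene dosages.
EXEMPT_CLASSES = ("exchange", "biomass", "atp-maintenance")

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


@dataclass
class Metabolite:
    """A metabolite species in a fixed compartment."""

    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None

    def elements(self) -> Dict[str, float]:
        """Parse the elemental formula into an element -> count map."""
        if not self.formula:
            return {}
        out: Dict[str, float] = {}
        for element, count in _ELEMENT_RE.findall(self.formula):
            if element:
                out[element] = out.get(element, 0.0) + (float(count) if count else 1.0)
        return out


@dataclass
class Reaction:
    """A reaction: stoichiometry (negative = consumed), bounds, GRR, class.

    Fluxes are in mmol/gDW/h; the biomass reaction's flux is the growth
    rate in 1/h.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    grr: GRRTree = NO_GENE
    subsystem: Optional[str] = None
    name: str = ""
    rxn_class: str = "internal"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset:
        return grr_mod.genes_in(self.grr)


class MetabolicNetwork:
    """A validated stoichiometric network with one biomass reaction."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        genes: Optional[Sequence[str]] = None,
        biomass_id: Optional[str] = None,
        id: str = "",
    ) -> None:
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        if genes is None:
            seen: Dict[str, None] = {}
            for rxn in self.reactions:
                for g in sorted(rxn.genes):
                    seen.setdefault(g, None)
            genes = list(seen)
        self.genes: List[str] = list(genes)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.biomass_id = self._resolve_biomass(biomass_id)
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _resolve_biomass(self, biomass_id: Optional[str]) -> str:
        declared = [r.id for r in self.reactions if r.rxn_class == "biomass"]
        if biomass_id is not None:
            if biomass_id not in self._rxn_index:
                raise ModelValidationError(f"biomass reaction {biomass_id!r} not in network")
            for r in self.reactions:
                if r.rxn_class == "biomass" and r.id != biomass_id:
                    r.rxn_class = "internal"
            self.reactions[self._rxn_index[biomass_id]].rxn_class = "biomass"
            return biomass_id
        if len(declared) != 1:
            raise ModelValidationError(
                f"expected exactly one biomass reaction, found {len(declared)}; "
                "pass biomass_id to disambiguate"
            )
        return declared[0]

    def _validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")
        gene_set = set(self.genes)
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(f"{rxn.id}: lower bound exceeds upper bound")
            if rxn.rxn_class not in REACTION_CLASSES:
                raise ModelValidationError(f"{rxn.id}: unknown class {rxn.rxn_class!r}")
            if rxn.rxn_class == "exchange" and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(f"{rxn.id}: exchange must involve one metabolite")
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(f"{rxn.id}: unknown metabolite {met_id!r}")
            unknown = rxn.genes - gene_set
            if unknown:
                raise ModelValidationError(
                    f"{rxn.id}: GRR references unknown gene(s) {sorted(unknown)}"
                )

    # -- queries --------------------------------------------------------------

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_id)

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.rxn_class == "exchange"]

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Metabolites x reactions stoichiometric matrix S."""
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                data.append(coef)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def default_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        """The model's native (lb, ub) arrays, aligned with ``reactions``."""
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def biomass_precursors(self) -> Dict[str, float]:
        """Metabolites consumed by the biomass reaction -> |stoich. coefficient|.

        These precursors encode the architecture of the growth phenotype.
        """
        return {
            met: -coef
            for met, coef in self.biomass_reaction.stoichiometry.items()
            if coef < 0
        }

    def summary(self) -> Dict[str, int]:
        return {
            "metabolites": len(self.metabolites),
            "reactions": len(self.reactions),
            "genes": len(self.genes),
            "exchanges": len(self.exchange_reactions),
        }


# -- cobra conversion and file I/O --------------------------------------------


def from_cobra(
    model,
    biomass_id: Optional[str] = None,
    atpm_ids: Sequence[str] = ("ATPM",),
) -> MetabolicNetwork:
    """Convert a ``cobra.Model`` into a :class:`MetabolicNetwork`.

    Reaction classes are inferred: single-metabolite boundary reactions are
    exchanges; the biomass reaction is the declared objective (or
    ``biomass_id``); ATP maintenance is matched by id against ``atpm_ids``.
    """
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "", m.formula or None)
        for m in model.metabolites
    ]
    objective_ids = {
        r.id for r in model.reactions if getattr(r, "objective_coefficient", 0.0)
    }
    reactions = []
    for r in model.reactions:
        rule = grr_mod.parse_grr(r.gene_reaction_rule)
        # class priority: declared biomass > ATP maintenance > exchange;
        # toy biomass reactions may be single-metabolite, so the objective
        # must win over the boundary heuristic
        if r.id in objective_ids or (biomass_id is not None and r.id == biomass_id):
            cls = "biomass"
        elif r.id in atpm_ids:
            cls = "atp-maintenance"
        elif len(r.metabolites) == 1:
            cls = "exchange"
        elif "biomass" in r.id.lower():
            cls = "biomass"
        else:
            cls = "internal"
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                grr=rule,
                subsystem=(r.subsystem or None),
                name=r.name or "",
                rxn_class=cls,
            )
        )
    genes = [g.id for g in model.genes]
    return MetabolicNetwork(mets, reactions, genes=genes, biomass_id=biomass_id, id=model.id or "")


def to_cobra(network: MetabolicNetwork):
    """Convert back to a ``cobra.Model`` (biomass set as the objective)."""
    import cobra

    model = cobra.Model(network.id or "metapgs_model")
    model.add_metabolites(
        [
            cobra.Metabolite(
                m.id, name=m.name, compartment=m.compartment or "c", formula=m.formula
            )
            for m in network.metabolites
        ]
    )
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in network.reactions:
        cr = model.reactions.get_by_id(r.id)
        cr.add_metabolites({model.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()})
        rule = grr_mod.to_string(r.grr)
        if rule:
            cr.gene_reaction_rule = rule
        if r.subsystem:
            cr.subsystem = r.subsystem
    model.objective = model.reactions.get_by_id(network.biomass_id)
    return model


def load_model(
    path,
    format: Optional[str] = None,
    biomass_id: Optional[str] = None,
    atpm_ids: Sequence[str] = ("ATPM",),
) -> MetabolicNetwork:
    """Load a genome-scale model from BiGG JSON or SBML (fbc).

    ``format`` is ``"bigg-json"`` or ``"sbml"``; when omitted it is inferred
    from the file suffix (.json vs .xml/.sbml).
    """
    import cobra.io

    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bigg-json" if suffix == ".json" else "sbml"
    try:
        if format == "bigg-json":
            model = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {format!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc
    return from_cobra(model, biomass_id=biomass_id, atpm_ids=atpm_ids)


def save_json(network: MetabolicNetwork, path) -> None:
    """Write the network as BiGG-style JSON (the canonical output dialect)."""
    import cobra.io

    cobra.io.save_json_model(to_cobra(network), str(path))


def gene_subsystem_map(network: MetabolicNetwork) -> Dict[str, Optional[str]]:
    """Impute one subsystem per gene, or ``None`` when ambiguous.

    A gene receives a subsystem only if every reaction it participates in
    carries that same (non-empty) subsystem annotation; genes spanning
    multiple subsystems, or only unannotated reactions, stay unassigned.
    """
    per_gene: Dict[str, set] = {g: set() for g in network.genes}
    for rxn in network.reactions:
        for g in rxn.genes:
            per_gene[g].add(rxn.subsystem)
    out: Dict[str, Optional[str]] = {}
    for gene, subsystems in per_gene.items():
        if len(subsystems) == 1:
            (only,) = subsystems
            out[gene] = only  # may be None if the only annotation is absent
        else:
            out[gene] = None
    return out
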