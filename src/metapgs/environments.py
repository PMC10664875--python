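"""Growth media: minimal, standard, and random environments.

The minimal medium opens unlimited import/export of the basal inorganic
components (water, CO2, ammonia, phosphate, sulfate, sodium, potassium)
and caps O2 import at 2 mmol/gDW/h (aerobic, avoiding fermentative
regimes); all other imports are closed and exports stay open.  The
standard medium adds glucose at up to 20 mmol/gDW/h.  Random media
supplement the minimal medium with carbon/nitrogen sources: one
inclusion probability p ~ Exp(mean m), truncated at 1, is drawn per
medium and applied independently to every candidate; included components
get import rates ~ U(0, 20).  Media are rejection-sampled into a
richness window relative to the standard medium (default 70%-100%),
where *richness* is the wild-type growth rate in that medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fba as fba_mod
from .exceptions import ConfigError, MediaGenerationError
from .model import MetabolicNetwork

__all__ = [
    "Medium",
    "EnvironmentConfig",
    "minimal_medium",
    "standard_medium",
    "random_media",
    "candidate_exchanges",
    "richness",
    "similarity",
    "UNLIMITED_RATE",
]

#: Conventional stand-in for an unlimited exchange rate (mmol/gDW/h).
UNLIMITED_RATE = 1000.0

#: Base metabolite ids (compartment suffix stripped) of the minimal medium.
MINIMAL_COMPONENT_IDS = ("h2o", "co2", "nh4", "pi", "so4", "na1", "k")
O2_ID = "o2"
GLUCOSE_IDS = ("glc__D", "glc_D")


@dataclass
class Medium:
    """Map exchange-reaction id -> maximal import rate (mmol/gDW/h)."""

    imports: Dict[str, float]
    name: str = ""
    richness: Optional[float] = None  # cached wild-type growth, 1/h

    def __post_init__(self) -> None:
        for rxn_id, rate in self.imports.items():
            if rate < 0:
                raise ConfigError(f"negative import rate for {rxn_id}")

    def with_imports(self, extra: Dict[str, float], name: str = "") -> "Medium":
        merged = dict(self.imports)
        merged.update(extra)
        return Medium(merged, name=name or self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"exchange_id": list(self.imports), "max_import": list(self.imports.values())}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class EnvironmentConfig:
    """Random-media generation parameters."""

    n: int
    m: float = 0.10  # mean of the exponential inclusion probability
    rate_range: Tuple[float, float] = (0.0, 20.0)
    richness_window: Tuple[float, float] = (0.7, 1.0)  # fractions of standard richness
    seed: Optional[int] = None
    min_acceptance: float = 1e-3

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.m <= 0:
            raise ConfigError("inclusion-probability mean m must be > 0")
        lo, hi = self.richness_window
        if not (0 < lo <= hi <= 1):
            raise ConfigError("richness window must lie within (0, 1]")


def _base_id(met_id: str, compartment: str) -> str:
    if compartment and met_id.endswith("_" + compartment):
        return met_id[: -(len(compartment) + 1)]
    return met_id


def _resolve_exchange(network: MetabolicNetwork, base_ids: Sequence[str]) -> Optional[str]:
    for rxn in network.exchange_reactions:
        (met_id,) = rxn.stoichiometry
        met = network.metabolite(met_id)
        if _base_id(met.id, met.compartment) in base_ids or met.id in base_ids:
            return rxn.id
    return None


def minimal_medium(
    network: MetabolicNetwork,
    components: Optional[Sequence[str]] = None,
    o2_exchange: Optional[str] = None,
    o2_rate: float = 2.0,
) -> Medium:
    """The aerobic minimal medium.

    ``components`` overrides the default basal set with explicit exchange
    reaction ids (needed for toy networks without yeast-like metabolite
    ids); ``o2_exchange=None`` with no resolvable O2 exchange simply
    omits the O2 cap (toy networks are not aerobic).
    """
    imports: Dict[str, float] = {}
    if components is not None:
        for rxn_id in components:
            if rxn_id not in {r.id for r in network.exchange_reactions}:
                raise ConfigError(f"{rxn_id!r} is not an exchange reaction")
            imports[rxn_id] = UNLIMITED_RATE
    else:
        for base in MINIMAL_COMPONENT_IDS:
            rxn_id = _resolve_exchange(network, (base,))
            if rxn_id is None:
                raise ConfigError(f"cannot resolve exchange for component {base!r}")
            imports[rxn_id] = UNLIMITED_RATE
    if o2_exchange is None and components is None:
        o2_exchange = _resolve_exchange(network, (O2_ID,))
        if o2_exchange is None:
            raise ConfigError("cannot resolve the O2 exchange reaction")
    if o2_exchange is not None:
        imports[o2_exchange] = o2_rate
    return Medium(imports, name="minimal")


def standard_medium(
    network: MetabolicNetwork,
    glucose_exchange: Optional[str] = None,
    glucose_rate: float = 20.0,
    minimal: Optional[Medium] = None,
    **minimal_kwargs,
) -> Medium:
    """Minimal medium plus glucose import at up to 20 mmol/gDW/h."""
    base = minimal if minimal is not None else minimal_medium(network, **minimal_kwargs)
    if glucose_exchange is None:
        glucose_exchange = _resolve_exchange(network, GLUCOSE_IDS)
        if glucose_exchange is None:
            raise ConfigError("cannot resolve the glucose exchange reaction")
    return base.with_imports({glucose_exchange: glucose_rate}, name="standard")


def candidate_exchanges(
    network: MetabolicNetwork,
    exclude: Sequence[str] = (),
    fallback: Optional[Sequence[str]] = None,
) -> List[str]:
    """Exchanges of carbon- or nitrogen-containing metabolites.

    Candidates for random-media supplementation; ``fallback`` supplies an
    explicit list when metabolite formulas are absent.
    """
    excluded = set(exclude)
    out = []
    for rxn in network.exchange_reactions:
        if rxn.id in excluded:
            continue
        (met_id,) = rxn.stoichiometry
        elements = network.metabolite(met_id).elements()
        if "C" in elements or "N" in elements:
            out.append(rxn.id)
    if not out and fallback is not None:
        out = [r for r in fallback if r not in excluded]
    return out


def richness(network: MetabolicNetwork, medium: Medium, ref=None) -> float:
    """Richness of a medium: wild-type (all dosages 1) pFBA growth in it.

    With ``ref`` given, the wild type is evaluated under its reference
    bounds; otherwise under the model's native bounds.  The value is
    cached on the medium.
    """
    instance = (
        fba_mod.reference_instance(network, ref) if ref is not None else network
    )
    medium.richness = float(fba_mod.pfba(instance, medium).growth)
    return medium.richness


def similarity(
    network: MetabolicNetwork, medium_a: Medium, medium_b: Medium, ref=None
) -> Optional[float]:
    """Environmental similarity: ratio of the two media's richness.

    Returns ``None`` when the denominator's richness is zero.
    """
    ra = medium_a.richness if medium_a.richness is not None else richness(network, medium_a, ref)
    rb = medium_b.richness if medium_b.richness is not None else richness(network, medium_b, ref)
    if rb == 0:
        return None
    return ra / rb


def random_media(
    network: MetabolicNetwork,
    config: EnvironmentConfig,
    ref=None,
    standard: Optional[Medium] = None,
    minimal: Optional[Medium] = None,
    candidates: Optional[Sequence[str]] = None,
) -> List[Medium]:
    """Rejection-sample ``config.n`` random media inside the richness window.

    Raises :class:`MediaGenerationError` when the acceptance rate falls
    below ``config.min_acceptance``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base = minimal if minimal is not None else minimal_medium(network)
    std = standard if standard is not None else standard_medium(network, minimal=base)
    r_std = std.richness if std.richness is not None else richness(network, std, ref)
    if r_std <= 0:
        raise MediaGenerationError("standard medium supports no growth")
    if candidates is None:
        # all C/N sources except the minimal-medium components; the standard
        # carbon source remains a legitimate candidate
        candidates = candidate_exchanges(network, exclude=list(base.imports))
    candidates = list(candidates)
    if not candidates:
        raise MediaGenerationError("no candidate carbon/nitrogen exchanges found")
    lo, hi = config.richness_window
    rate_lo, rate_hi = config.rate_range

    accepted: List[Medium] = []
    attempts = 0
    min_attempts = 200
    while len(accepted) < config.n:
        attempts += 1
        if attempts > min_attempts and len(accepted) / attempts < config.min_acceptance:
            raise MediaGenerationError(
                f"acceptance rate {len(accepted)}/{attempts} below "
                f"{config.min_acceptance}; window={config.richness_window}, "
                f"m={config.m}, candidates={len(candidates)}"
            )
        p = min(1.0, rng.exponential(config.m))
        mask = rng.random(len(candidates)) < p
        rates = rng.uniform(rate_lo, rate_hi, size=len(candidates))
        extra = {c: float(r) for c, r, keep in zip(candidates, rates, mask) if keep}
        medium = base.with_imports(extra, name=f"random_{len(accepted)}")
        r_med = richness(network, medium, ref)
        if lo * r_std <= r_med <= hi * r_std:
            accepted.append(medium)
    return accepted
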