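"""In-silico populations of relative gene dosages.

Genetic variation is modeled as i.i.d. per-gene, per-individual draws of
relative dosages (linkage equilibrium), following the infinitesimal-model
rationale.  The standard population draws from a normal distribution with
mean 1 and sd sigma = 0.1; dosages above 1 are trimmed to 1 (the wild-type
reference bound is the statistical extreme, so higher dosage confers no
benefit) and negative draws are clipped to 0 (dosages are physical
fractions).  A mean-matched gamma family (shape 0.5 < k < 200, rescaled to
the target mean before trimming) provides skewed alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = [
    "PopulationConfig",
    "GenotypeMatrix",
    "sample_population",
    "realized_variation",
    "population_sampler",
]


@dataclass
class PopulationConfig:
    """Sampling parameters for one population of dosage vectors."""

    n: int
    family: str = "normal"  # "normal" | "gamma"
    sigma: float = 0.1  # normal sd
    k: Optional[float] = None  # gamma shape
    mean: float = 1.0  # target (pre-trim) mean
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("population size must be >= 1")
        if self.family == "normal":
            if self.sigma < 0:
                raise ConfigError("sigma must be nonnegative")
        elif self.family == "gamma":
            if self.k is None or not (0.5 < self.k < 200):
                raise ConfigError("gamma shape k must satisfy 0.5 < k < 200")
        else:
            raise ConfigError(f"unknown distribution family {self.family!r}")


@dataclass
class GenotypeMatrix:
    """N individuals x M genes matrix of relative dosages in [0, 1]."""

    values: np.ndarray
    genes: List[str]
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.genes):
            raise ConfigError("genotype matrix shape does not match gene list")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def row(self, i: int) -> Dict[str, float]:
        return dict(zip(self.genes, self.values[i]))

    def iter_rows(self):
        for i in range(len(self)):
            yield self.row(i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.genes)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), list(df.columns))

    def subset(self, rows) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[rows], list(self.genes), dict(self.provenance))


def _draw(config: PopulationConfig, size, rng: np.random.Generator) -> np.ndarray:
    if config.family == "normal":
        raw = rng.normal(config.mean, config.sigma, size=size)
    else:
        # gamma rescaled so the pre-trim mean equals the target mean;
        # variance = mean^2 / k, so large k approaches the wild type
        raw = rng.gamma(config.k, scale=config.mean / config.k, size=size)
    return np.clip(raw, 0.0, 1.0)


def sample_population(
    config: PopulationConfig,
    genes: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Sample an N x M genotype matrix of trimmed dosages."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    values = _draw(config, (config.n, len(genes)), rng)
    provenance = {
        "family": config.family,
        "sigma": config.sigma,
        "k": config.k,
        "mean": config.mean,
        "seed": config.seed,
        "n": config.n,
    }
    return GenotypeMatrix(values, list(genes), provenance)


def realized_variation(G: GenotypeMatrix) -> float:
    """Realized genetic variation sigma_G: sd over all post-trim entries."""
    if len(G) < 2:
        raise ConfigError("need at least 2 individuals")
    return float(np.std(G.values))


def population_sampler(
    config: PopulationConfig, n_genes: int
) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Row sampler drawing from the population's dosage distribution.

    Used by the Sobol machinery, which needs fresh genotype draws from
    the same generative process as the study population.
    """
    config.validate()

    def sample(n: int, rng: np.random.Generator) -> np.ndarray:
        return _draw(config, (n, n_genes), rng)

    return sample
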