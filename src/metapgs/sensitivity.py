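"""Variance-based global sensitivity analysis of the dosage -> growth map.

For each gene i the first-order Sobol index S0_i measures the additive
share of growth variance attributable to its dosage alone, and the
total-effect index ST_i the share including all interactions.  Their
difference eT_i = ST_i - S0_i is the *total epistasis* of the gene: all,
and only, its non-additive contribution.  Indices are estimated with the
Saltelli pick-freeze scheme (Sobol-Saltelli estimator for S0, Jansen
estimator for ST) on pairs of genotype matrices drawn from the study
population's dosage distribution, with row-bootstrap error bars.  An
exact grid-enumeration decomposition is provided as an oracle for small
gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError, MetaPGSError

__all__ = [
    "SobolIndices",
    "sobol_indices",
    "brute_force_decomposition",
    "correlate_with_effect_sizes",
]


@dataclass
class SobolIndices:
    """Per-gene S0, ST, eT with Monte Carlo errors.

    ``table`` columns: S0, dS0, ST, dST, eT, deT.  Reported S0 and eT
    are truncated at 0 (negative estimates are sampling noise around a
    null value); ``raw`` keeps the untruncated estimates.
    """

    table: pd.DataFrame
    raw: pd.DataFrame
    n_base: int
    seed: Optional[int]
    estimator: str = "saltelli-2010/jansen-1999"

    @property
    def genes(self) -> List[str]:
        return list(self.table.index)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")


def _estimates(fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """S0 and ST estimators from pick-freeze evaluations.

    fA, fB: (n,) base evaluations; fAB: (m, n) with row i = f on A with
    column i replaced from B.
    """
    f_all = np.concatenate([fA, fB])
    V = f_all.var()
    if V <= 0:
        raise MetaPGSError("phenotype variance is zero; Sobol indices undefined")
    # centering leaves the expectation unchanged but suppresses the Monte
    # Carlo variance blow-up when the output mean dwarfs its spread
    mu = f_all.mean()
    S0 = ((fB - mu) * (fAB - fA)).mean(axis=1) / V
    ST = 0.5 * ((fA - fAB) ** 2).mean(axis=1) / V
    return S0, ST


def sobol_indices(
    phenotype_fn: Callable[[np.ndarray], np.ndarray],
    sampler: Callable[[int, np.random.Generator], np.ndarray],
    n_base: int,
    seed: Optional[int] = None,
    genes: Optional[Sequence[str]] = None,
    n_boot: int = 200,
    truncate: bool = True,
) -> SobolIndices:
    """Monte Carlo Sobol indices for a deterministic phenotype function.

    ``phenotype_fn`` maps an (n, M) dosage matrix to n growth values;
    ``sampler(n, rng)`` draws dosage matrices from the population's
    distribution.  Cost: (M + 2) * n_base phenotype evaluations.
    Errors are bootstrap standard deviations over sample rows, with
    deT = sqrt(dS0^2 + dST^2).
    """
    if n_base < 2:
        raise ConfigError("n_base must be >= 2")
    rng = np.random.default_rng(seed)
    A = np.asarray(sampler(n_base, rng), dtype=float)
    B = np.asarray(sampler(n_base, rng), dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ConfigError("sampler must return (n, M) matrices")
    m = A.shape[1]
    if genes is None:
        genes = [f"g{i + 1}" for i in range(m)]
    if len(genes) != m:
        raise ConfigError("gene list length does not match sampler width")

    fA = np.asarray(phenotype_fn(A), dtype=float)
    fB = np.asarray(phenotype_fn(B), dtype=float)
    fAB = np.empty((m, n_base))
    for i in range(m):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = phenotype_fn(ABi)

    S0, ST = _estimates(fA, fB, fAB)

    boot_S0 = np.empty((n_boot, m))
    boot_ST = np.empty((n_boot, m))
    for b in range(n_boot):
        idx = rng.integers(0, n_base, size=n_base)
        boot_S0[b], boot_ST[b] = _estimates(fA[idx], fB[idx], fAB[:, idx])
    dS0 = boot_S0.std(axis=0, ddof=1)
    dST = boot_ST.std(axis=0, ddof=1)
    deT = np.sqrt(dS0**2 + dST**2)

    eT = ST - S0
    raw = pd.DataFrame(
        {"S0": S0, "dS0": dS0, "ST": ST, "dST": dST, "eT": eT, "deT": deT},
        index=list(genes),
    )
    table = raw.copy()
    if truncate:
        table["S0"] = table["S0"].clip(lower=0.0)
        table["eT"] = table["eT"].clip(lower=0.0)
        table["ST"] = table["ST"].clip(lower=0.0)
    return SobolIndices(table=table, raw=raw, n_base=n_base, seed=seed)


def brute_force_decomposition(
    phenotype_fn: Callable[[np.ndarray], np.ndarray],
    grids: Sequence[np.ndarray],
    max_cells: int = 200_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact variance decomposition on a full tensor grid (oracle).

    Enumerates the product of per-gene dosage grids (uniform weight per
    grid point), evaluates the phenotype everywhere, and computes
    S0_i = Var(E[y|g_i]) / Var(y) and ST_i = 1 - Var(E[y|g_-i]) / Var(y)
    under the grid measure.  Intended for <= 6 genes x <= 21 levels.
    """
    grids = [np.asarray(g, dtype=float) for g in grids]
    m = len(grids)
    shape = tuple(len(g) for g in grids)
    n_cells = int(np.prod(shape))
    if n_cells > max_cells:
        raise ConfigError(f"grid too large ({n_cells} cells > {max_cells})")
    mesh = np.meshgrid(*grids, indexing="ij")
    X = np.column_stack([mg.ravel() for mg in mesh])
    y = np.asarray(phenotype_fn(X), dtype=float).reshape(shape)
    V = y.var()
    if V <= 0:
        raise MetaPGSError("phenotype variance is zero on the grid")
    S0 = np.empty(m)
    ST = np.empty(m)
    axes = tuple(range(m))
    for i in range(m):
        others = tuple(a for a in axes if a != i)
        cond_mean_i = y.mean(axis=others)  # E[y | g_i]
        S0[i] = cond_mean_i.var() / V
        cond_mean_not_i = y.mean(axis=i)  # E[y | g_-i]
        ST[i] = 1.0 - cond_mean_not_i.var() / V
    return S0, ST


def correlate_with_effect_sizes(
    indices: SobolIndices,
    model,
    strong_genes: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """Pearson correlations of S0, eT and S0+eT against the PGS betas.

    Returns rho_S0, rho_eT, rho_total over all genes and, when
    ``strong_genes`` is given, the same restricted to that subset
    (keys suffixed ``_strong``).
    """
    beta = model.beta
    common = [g for g in indices.genes if g in beta.index]
    if len(common) < 3:
        raise ConfigError("need at least 3 shared genes")
    tab = indices.table.loc[common]
    b = beta.loc[common].to_numpy()

    def rho(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    out = {
        "rho_S0": rho(tab["S0"].to_numpy(), b),
        "rho_eT": rho(tab["eT"].to_numpy(), b),
        "rho_total": rho((tab["S0"] + tab["eT"]).to_numpy(), b),
    }
    if strong_genes is not None:
        sub = [g for g in strong_genes if g in common]
        if len(sub) >= 3:
            ts = indices.table.loc[sub]
            bs = beta.loc[sub].to_numpy()
            out["rho_S0_strong"] = rho(ts["S0"].to_numpy(), bs)
            out["rho_eT_strong"] = rho(ts["eT"].to_numpy(), bs)
            out["rho_total_strong"] = rho((ts["S0"] + ts["eT"]).to_numpy(), bs)
    return out
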