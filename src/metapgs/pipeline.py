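"""End-to-end experiment orchestration with seeds and cached intermediates.

Each experiment composes the library's stages — population sampling,
dosage-constrained pFBA phenotypes, PGS training, sensitivity and
mechanistic dissection — into a deterministic result bundle of tables
keyed by name.  Experiments run on a toy scenario (no downloads) or on
a genome-scale model file declared in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import environments as env_mod
from . import fba as fba_mod
from . import model as model_mod
from . import mutations as mut_mod
from . import pgs as pgs_mod
from . import sensitivity as sens_mod
from . import systemic as sys_mod
from .exceptions import ConfigError
from .fixtures import ToyScenario
from .population import PopulationConfig, population_sampler, realized_variation, sample_population

__all__ = ["ExperimentConfig", "run_experiment", "partial_correlation", "EXPERIMENTS"]

EXPERIMENTS = (
    "fig2-core",
    "fig3-precursors",
    "fig4-sensitivity",
    "fig5-sigma-sweep",
    "fig6-environments",
    "fig7-bounds",
)


@dataclass
class ExperimentConfig:
    """Configuration shared by all experiments.

    Either ``scenario`` (a toy scenario object) or ``model_path`` must
    be provided; with a model path, reference bounds are computed from a
    random-environment ensemble of ``n_ref_media`` media.
    """

    seed: int
    scenario: Optional[ToyScenario] = None
    model_path: Optional[str] = None
    n_ref_media: int = 100
    bound_range: Tuple[float, float] = (0.0, 100.0)
    n_individuals: int = 400
    family: str = "normal"
    sigma: float = 0.1
    gamma_k: Optional[float] = None
    pgs_method: str = "lasso"
    strong_threshold: float = pgs_mod.STRONG_THRESHOLD
    sobol_n_base: int = 4096
    sigma_grid: Tuple[float, ...] = tuple(np.logspace(np.log10(0.01), np.log10(0.5), 10))
    n_environments: int = 30
    env_m: float = 0.10
    n_coupling_iterations: int = 10
    coupling_group_size: Tuple[int, int] = (1, 3)
    n_pleiotropy_individuals: int = 8
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigError("config requires an explicit seed")
        return cls(**raw)

    def child_seed(self, stream: int) -> int:
        return int(np.random.SeedSequence([self.seed, stream]).generate_state(1)[0] % (2**31))


def _prepare(config: ExperimentConfig, cache: Dict) -> Tuple:
    """(network, ref, medium, genes) from scenario or model file, cached."""
    if "prepared" in cache:
        return cache["prepared"]
    if config.scenario is not None:
        sc = config.scenario
        prepared = (sc.network, sc.ref, sc.medium, list(sc.genes))
    elif config.model_path is not None:
        network = model_mod.load_model(config.model_path)
        ref = mut_mod.compute_reference_bounds(
            network,
            n_media=config.n_ref_media,
            bound_range=config.bound_range,
            rng_seed=config.child_seed(0),
        )
        medium = env_mod.standard_medium(network)
        prepared = (network, ref, medium, list(network.genes))
    else:
        raise ConfigError("config needs a scenario or a model_path")
    cache["prepared"] = prepared
    return prepared


def _population_and_phenotypes(config: ExperimentConfig, cache: Dict):
    if "dataset" in cache:
        return cache["dataset"]
    network, ref, medium, genes = _prepare(config, cache)
    G = sample_population(
        PopulationConfig(
            n=config.n_individuals,
            family=config.family,
            sigma=config.sigma,
            k=config.gamma_k,
            seed=config.child_seed(1),
        ),
        genes,
    )
    y, solutions = mut_mod.population_phenotypes(
        network, ref, G, medium, return_solutions=True
    )
    cache["dataset"] = (G, y, solutions)
    return cache["dataset"]


def _pgs(config: ExperimentConfig, cache: Dict) -> pgs_mod.PGSModel:
    if "pgs" not in cache:
        G, y, _ = _population_and_phenotypes(config, cache)
        cache["pgs"] = pgs_mod.train_pgs(
            G, y, method=config.pgs_method, seed=config.child_seed(2)
        )
    return cache["pgs"]


def _fig2(config: ExperimentConfig, cache: Dict) -> Dict[str, pd.DataFrame]:
    network, ref, medium, genes = _prepare(config, cache)
    G, y, solutions = _population_and_phenotypes(config, cache)
    model = _pgs(config, cache)
    classes = pgs_mod.classify_effects(model, config.strong_threshold)
    stats = fba_mod.population_flux_stats(solutions)
    unused = [fba_mod.unused_flux_fraction(s) for s in solutions if s.feasible]
    effects = pd.DataFrame(
        {"beta": model.beta, "effect_class": classes.classes}
    ).rename_axis("gene")
    summary = pd.DataFrame(
        [
            {
                "mean_growth": float(np.mean(y)),
                "sd_growth": float(np.std(y)),
                "wildtype_growth": env_mod.richness(network, medium, ref),
                "r2_train": model.r2_train,
                "cv_r2_mean": model.cv_r2_mean,
                "sigma_G": realized_variation(G),
                "mean_unused_flux_fraction": float(np.mean(unused)),
                "n_null": classes.counts["null"],
                "n_weak": classes.counts["weak"],
                "n_strong": classes.counts["strong"],
            }
        ]
    )
    return {
        "population": G.to_frame(),
        "phenotypes": pd.DataFrame({"growth": y}),
        "effects": effects,
        "flux_cv": stats["cv"].rename_axis("reaction_id").to_frame(),
        "mean_metabolism": stats["mean_flux"].rename_axis("reaction_id").to_frame(),
        "summary": summary,
    }


def _fig3(config: ExperimentConfig, cache: Dict) -> Dict[str, pd.DataFrame]:
    network, _, _, _ = _prepare(config, cache)
    _, _, solutions = _population_and_phenotypes(config, cache)
    model = _pgs(config, cache)
    strong = pgs_mod.classify_effects(model, config.strong_threshold).strong_genes()
    if not strong:  # fall back to the largest-effect gene so xi is defined
        strong = [model.beta.abs().idxmax()]
    xi = sys_mod.precursor_contribution(
        network, solutions, strong, seed=config.child_seed(3)
    )
    return {"xi": xi.rename_axis("precursor"), "strong_genes": pd.DataFrame({"gene": strong})}


def _fig4(config: ExperimentConfig, cache: Dict) -> Dict[str, pd.DataFrame]:
    network, ref, medium, genes = _prepare(config, cache)
    model = _pgs(config, cache)
    G, _, _ = _population_and_phenotypes(config, cache)
    sampler = population_sampler(
        PopulationConfig(
            n=1, family=config.family, sigma=config.sigma, k=config.gamma_k
        ),
        len(genes),
    )
    if config.scenario is not None:
        phen = lambda M: config.scenario.analytic_growth(M)  # noqa: E731
    else:
        from .population import GenotypeMatrix

        def phen(M):
            return mut_mod.population_phenotypes(
                network, ref, GenotypeMatrix(M, genes), medium
            )

    indices = sens_mod.sobol_indices(
        phen, sampler, n_base=config.sobol_n_base, seed=config.child_seed(4), genes=genes
    )
    strong = pgs_mod.classify_effects(model, config.strong_threshold).strong_genes()
    rho = sens_mod.correlate_with_effect_sizes(indices, model, strong_genes=strong or None)
    n_pl = min(config.n_pleiotropy_individuals, len(G))
    pleio = sys_mod.pleiotropy(network, ref, G.subset(range(n_pl)), medium)
    tables = {
        "sobol": indices.table.rename_axis("gene"),
        "correlations": pd.DataFrame([rho]),
        "pleiotropy": pd.DataFrame(
            {"mean": pleio.mean, "sd": pleio.sd}
        ).rename_axis("gene"),
    }
    if strong:
        tables["pleiotropic_impact"] = sys_mod.pleiotropic_impact(
            pleio, strong, seed=config.child_seed(5)
        ).rename_axis("precursor")
    return tables


def _fig5(config: ExperimentConfig, cache: Dict) -> Dict[str, pd.DataFrame]:
    network, ref, medium, genes = _prepare(config, cache)
    rows = []
    for i, sigma in enumerate(config.sigma_grid):
        G = sample_population(
            PopulationConfig(
                n=config.n_individuals, sigma=float(sigma), seed=config.child_seed(100 + i)
            ),
            genes,
        )
        if config.scenario is not None:
            y = config.scenario.analytic_growth(G)
        else:
            y = mut_mod.population_phenotypes(network, ref, G, medium)
        try:
            model = pgs_mod.train_pgs(
                G, y, method=config.pgs_method, seed=config.child_seed(2),
                compute_cv_r2=False,
            )
            r2 = model.r2_train
            n_strong = len(
                pgs_mod.classify_effects(model, config.strong_threshold).strong_genes()
            )
        except pgs_mod.DegenerateFitError:
            r2, n_strong = float("nan"), 0
        rows.append(
            {
                "sigma": float(sigma),
                "sigma_G": realized_variation(G),
                "mean_growth": float(np.mean(y)),
                "r2": r2,
                "n_strong": n_strong,
            }
        )
    return {"sigma_sweep": pd.DataFrame(rows)}


def _fig6(config: ExperimentConfig, cache: Dict) -> Dict[str, pd.DataFrame]:
    network, ref, medium, genes = _prepare(config, cache)
    G, y, _ = _population_and_phenotypes(config, cache)
    model_std = _pgs(config, cache)
    env_cfg = env_mod.EnvironmentConfig(
        n=config.n_environments, m=config.env_m, seed=config.child_seed(6)
    )
    # toy scenarios have no resolvable basal components: their minimal
    # medium is empty and the scenario medium plays the standard role
    minimal = env_mod.Medium({}, name="minimal") if config.scenario is not None else None
    media = env_mod.random_media(
        network, env_cfg, ref=ref, standard=medium, minimal=minimal,
    )
    port = pgs_mod.portability_experiment(
        model_std, network, ref, G, media, medium,
        method=config.pgs_method, threshold=config.strong_threshold,
        seed=config.child_seed(2),
    )
    theta_rows = []
    for medium_i in media:
        y_i = mut_mod.population_phenotypes(network, ref, G, medium_i)
        try:
            model_i = pgs_mod.train_pgs(
                G, y_i, method=config.pgs_method, seed=config.child_seed(2),
                compute_cv_r2=False,
            )
            theta_rows.append(
                {
                    "medium": medium_i.name,
                    "richness": medium_i.richness,
                    "r2": model_i.r2_train,
                    "theta_max": pgs_mod.theta_max(model_i),
                }
            )
        except pgs_mod.DegenerateFitError:
            theta_rows.append(
                {"medium": medium_i.name, "richness": medium_i.richness,
                 "r2": float("nan"), "theta_max": float("nan")}
            )
    return {"portability": port, "per_medium_pgs": pd.DataFrame(theta_rows)}


def _fig7(config: ExperimentConfig, cache: Dict) -> Dict[str, pd.DataFrame]:
    network, ref, medium, genes = _prepare(config, cache)
    G, y, _ = _population_and_phenotypes(config, cache)
    table = sys_mod.coupling_experiment(
        network, ref, G, medium,
        n_iterations=config.n_coupling_iterations,
        group_size_range=config.coupling_group_size,
        seed=config.child_seed(7),
        method=config.pgs_method,
        threshold=config.strong_threshold,
    )
    return {"coupling": table}


_DISPATCH = {
    "fig2-core": _fig2,
    "fig3-precursors": _fig3,
    "fig4-sensitivity": _fig4,
    "fig5-sigma-sweep": _fig5,
    "fig6-environments": _fig6,
    "fig7-bounds": _fig7,
}


def run_experiment(
    name: str, config: ExperimentConfig, cache: Optional[Dict] = None
) -> Dict[str, pd.DataFrame]:
    """Run one named experiment; deterministic given ``config.seed``.

    ``cache`` (a plain dict) carries intermediates — reference bounds,
    population, flux solutions, the trained PGS — across experiments
    sharing a config.  With ``config.outdir`` set, tables are written as
    TSV under ``outdir/<experiment>/``.
    """
    if name not in _DISPATCH:
        raise ConfigError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    if cache is None:
        cache = {}
    tables = _DISPATCH[name](config, cache)
    if config.outdir:
        out = Path(config.outdir) / name
        out.mkdir(parents=True, exist_ok=True)
        for key, df in tables.items():
            df.to_csv(out / f"{key}.tsv", sep="\t")
        meta = asdict(config)
        meta.pop("scenario", None)
        with open(out / "config.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)
    return tables


def partial_correlation(x, y, control) -> float:
    """Pearson correlation of x and y after removing a control variable.

    Both x and y are regressed (OLS, with intercept) on the control; the
    residuals are correlated.  Returns NaN when either residual vector
    is degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (len(x) == len(y) == len(c)) or len(x) < 4:
        raise ConfigError("need equal-length vectors with n >= 4")
    A = np.column_stack([c, np.ones_like(c)])

    def resid(v):
        coef = np.linalg.lstsq(A, v, rcond=None)[0]
        return v - A @ coef

    rx, ry = resid(x), resid(y)
    if np.std(rx) < 1e-12 or np.std(ry) < 1e-12:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])
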