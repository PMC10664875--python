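#!/usr/bin/env python
"""Scaled-down reproduction of the yeast (iND750) study.

Requires the iND750 BiGG JSON model, e.g. from the BiGG database
(http://bigg.ucsd.edu/models/iND750); it is not bundled.  The defaults
are scaled down (500 ensemble media, 500 individuals) to finish in tens
of minutes on one CPU; raise --n-ref-media / --n-individuals toward
2x10^4 / 5x10^3 for the full-scale run.

Usage:
    python scripts/reproduce_yeast.py --model iND750.json --seed 1
"""

import argparse
import json
from pathlib import Path

import numpy as np

import metapgs as mp
from metapgs.population import PopulationConfig, realized_variation, sample_population


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", required=True, help="path to the iND750 BiGG JSON")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-ref-media", type=int, default=500)
    parser.add_argument("--n-individuals", type=int, default=500)
    parser.add_argument("--sobol-n-base", type=int, default=0,
                        help="Sobol base sample size (0 disables the sensitivity stage)")
    parser.add_argument("--out", default="results/yeast")
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)

    network = mp.load_model(args.model)
    print(f"model: {network.id or args.model} — {network.summary()}")

    medium = mp.standard_medium(network)
    print("computing reference bounds from the random-environment ensemble ...")
    ref = mp.compute_reference_bounds(
        network, n_media=args.n_ref_media, rng_seed=int(rng.integers(2**31))
    )
    wt = mp.richness(network, medium, ref=ref)
    print(f"wild-type growth in the standard medium: {wt:.3f} 1/h")

    G = sample_population(
        PopulationConfig(n=args.n_individuals, sigma=0.1, seed=int(rng.integers(2**31))),
        network.genes,
    )
    print(f"population: {len(G)} individuals, sigma_G = {realized_variation(G):.3f}")
    y, sols = mp.population_phenotypes(network, ref, G, medium, return_solutions=True)
    unused = float(np.mean([mp.unused_flux_fraction(s) for s in sols if s.feasible]))
    print(f"mean growth {np.mean(y):.3f} ± {np.std(y):.3f} 1/h; "
          f"unused flux fraction {unused:.2f}")

    model = mp.train_pgs(G, y, method="lasso", seed=args.seed)
    classes = mp.classify_effects(model, threshold=0.01)
    print(f"LASSO PGS: R2_train = {model.r2_train:.3f}, "
          f"5-fold CV R2 = {model.cv_r2_mean:.3f} ± {model.cv_r2_sd:.3f}")
    print(f"effect classes: {classes.counts} "
          f"({len(classes.nonnull_genes())} non-null)")

    summary = {
        "wildtype_growth": wt,
        "mean_growth": float(np.mean(y)),
        "sd_growth": float(np.std(y)),
        "unused_flux_fraction": unused,
        "r2_train": model.r2_train,
        "cv_r2_mean": model.cv_r2_mean,
        "n_nonnull": len(classes.nonnull_genes()),
        "n_strong": classes.counts["strong"],
        "sigma_G": realized_variation(G),
    }

    if args.sobol_n_base > 0:
        from metapgs.population import GenotypeMatrix

        def phen(M):
            return mp.population_phenotypes(
                network, ref, GenotypeMatrix(M, network.genes), medium
            )

        sampler = mp.population_sampler(PopulationConfig(n=1, sigma=0.1), len(network.genes))
        idx = mp.sobol_indices(
            phen, sampler, n_base=args.sobol_n_base,
            seed=int(rng.integers(2**31)), genes=network.genes,
        )
        rho = mp.correlate_with_effect_sizes(idx, model, strong_genes=classes.strong_genes())
        print(f"rho(S0 + eT, beta) = {rho['rho_total']:.3f}")
        summary.update(rho)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    model.to_json(out / "pgs.json")
    ref.to_tsv(out / "reference_bounds.tsv", provenance_path=out / "reference_bounds.json")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
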