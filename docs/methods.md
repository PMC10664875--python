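# Methods

## The genotype → phenotype map

An individual is a vector of relative gene dosages g ∈ [0, 1]^M over
the M genes of a genome-scale metabolic reconstruction. Dosage is an
abstraction of expression level / enzyme efficiency relative to the
wild type (g = 1); it never exceeds 1 because the wild-type reference
bounds are, by construction, the statistical extremes of flux (see
below), so extra enzyme confers no benefit.

**Rule evaluation.** Each reaction's gene-reaction rule is parsed into
an n-ary AND/OR tree (cobrapy's GPR parser does the tokenizing; AND
binds tighter than OR, matching BiGG convention). The quantitative
reading maps AND → min of the children (a complex is limited by its
scarcest subunit) and OR → sum of the children (isozymes pool
capacity), clipped at 1. Clipping is applied at each OR node; for trees
whose leaves lie in [0, 1] this is provably identical to a single final
clip, and it keeps the multiplier δ_r nondecreasing in every dosage —
the source of the map's monotonicity (growth never increases when any
dosage decreases, verified by LP dominance tests).

**Reference ("historical") bounds.** For each internal reaction the
wild-type bound is the extreme flux observed across an ensemble of
2·n_media pFBA solutions: for each of n_media random media, one solve
with the model's native bounds and one with every internal upper bound
resampled uniformly from [0, 100] mmol/gDW/h (reversible lower bounds
get the negated draw; the sampling of reversible lower bounds is not
independently randomized — a deliberate simplification recorded here).
f_r^ub is the maximum flux (floored at 0: a reaction never active in
the ensemble stays permanently closed), f_r^lb the minimum (capped at
0) when the reaction is reversible, else 0. Infeasible ensemble samples
are skipped, not imputed; the realized solve count is kept in the
provenance. Exchange, biomass and ATP-maintenance reactions are exempt
everywhere and keep their model bounds (ATP maintenance is matched by
the conventional id `ATPM`, overridable). A mutant's working bounds are
δ_r·f_r^ub and, for reversible reactions, δ_r·f_r^lb.

**Phenotype.** Growth is the biomass flux of a parsimonious FBA
solution: stage 1 maximizes biomass subject to S·v = 0 and the bounds;
stage 2 pins growth at the optimum (relative slack 10⁻⁹) and minimizes
Σ|v| by forward/reverse flux splitting. Both stages run on scipy's
HiGHS solver; solutions record the solver tolerance (10⁻⁹ feasibility)
and satisfy max|S·v| ≤ 10⁻⁶ by test. pFBA is the canonical phenotype
(it picks a reproducible point among degenerate FBA optima); plain FBA
is used where the objective is not growth, e.g. maximal metabolite
export in the pleiotropy score. Reported growth is the stage-1 optimum;
the stage-2 flux vector's biomass entry may sit ≤ 10⁻⁸ below it.

## Populations and environments

Dosages are i.i.d. per gene and individual (linkage equilibrium), from
a normal with mean 1 and σ = 0.1 by default, trimmed to 1 above and
clipped to 0 below (negative dosages are unphysical; the paper-level
convention only specifies the upper trim). The realized variation σ_G
is the sd of all post-trim entries; for the standard population the
analytic value is 0.1·sqrt(1/2 − 1/(2π)) ≈ 0.058. A gamma family
(shape 0.5 < k < 200, rescaled to the target mean before trimming)
provides skewed alternatives with variance mean²/k.

Media assign maximal import rates to exchange reactions; unlisted
imports are closed and exports stay open. The minimal medium opens
water, CO₂, ammonia, phosphate, sulfate, sodium and potassium without
limit and caps O₂ at 2 mmol/gDW/h (aerobic; the O₂ cap is the sole
guard against fermentative regimes). The standard medium adds glucose
at 20 mmol/gDW/h. Random media supplement the minimal medium with
carbon/nitrogen sources (detected from metabolite formulas, with an
explicit candidate list as fallback): one inclusion probability
p ~ Exp(mean 0.10), truncated at 1, is drawn *per medium* and applied
independently per candidate — the per-medium draw produces the wide
richness spread the environment experiments need; a per-component draw
was the considered alternative. Included components get rates
~ U(0, 20). Media are rejection-sampled into the 70–100% window of the
standard medium's richness (richness = wild-type pFBA growth in the
medium); generation aborts with diagnostics if acceptance falls below
10⁻³.

## Polygenic scores

y⃗ = **G** β⃗ + intercept + ε⃗, fit by LASSO with the shrinkage
parameter chosen by 5-fold cross-validation over 100 auto-scaled
alphas (OLS, ridge, elastic net with l1_ratio 0.5 as alternatives).
Predictors are standardized internally for penalized fits and β is
back-transformed to the dosage scale, so the |β| > 0.01 h⁻¹ strong-
predictor threshold is meaningful in physical units. Two R² values are
reported: R²_train on the full training set at the selected shrinkage,
and the held-out 5-fold CV mean ± sd under the same folds (the two
differ slightly by construction; both are exposed rather than choosing
one). Transfer R² uses the plain coefficient of determination with the
test-set variance in the denominator and may be negative; it is never
clipped. Effect classes: null (β = 0 to 10⁻¹² tolerance), weak, strong.
θ_max, the gene–environment outlier statistic, is the z-score of the
largest |β| against the mean and population (ddof 0) sd of all |β|;
it is undefined (NaN) when effect sizes are all equal. A constant
phenotype raises a degenerate-fit error rather than returning a
meaningless fit.

## Global sensitivity and total epistasis

First-order and total-effect Sobol indices are estimated with the
pick-freeze scheme: two base dosage matrices A, B plus per-gene hybrids
A_B^(i), with the Sobol–Saltelli estimator for S₀ (mean-centered — the
centering leaves the expectation unchanged but is essential numerically
when the phenotype's mean dwarfs its variance, as it does for mildly
varying populations) and the Jansen estimator for S_T. Total epistasis
is ε_T = S_T − S₀ with error propagated as Δε_T² = ΔS₀² + ΔS_T².
Errors are bootstrap sds over 200 row resamples. Inputs are sampled
from the study population's dosage distribution, not from a uniform
box. Reported S₀ and ε_T are truncated at 0 (negative estimates are
sampling noise around a null value); untruncated estimates are kept in
`raw`. An exact tensor-grid decomposition (≤ 6 genes, ≤ 21 levels,
uniform grid measure) serves as the oracle the estimator is tested
against.

## Mechanistic dissection

*Pleiotropy* of a gene: the number of biomass precursors whose maximal
producibility (a temporary export reaction, maximized by plain FBA)
drops by more than 10⁻³ relative when the gene's dosage is reduced by
90%, averaged over a genotype subset. The 90% knockdown avoids the
degenerate all-or-nothing behavior of full deletions; the 10⁻³
tolerance separates genuine limitation from LP noise. Precursors not
producible in any background are excluded with a warning.

*Precursor contribution* ξ of a gene set, per precursor: the
population mean of (production of the precursor by reactions carrying
at least one set gene) / (biomass flux × the precursor's biomass
coefficient), in percent. A reaction shared by several set members is
counted once (set-level aggregation; no double counting), and the
normalization uses each individual's own biomass flux. Significance is
assessed against size-matched random gene sets; the empirical p-value
uses uniform tie-breaking, p = (#{null > obs} + U·(1 + #{null =
obs}))/(n + 1), which is exactly U(0,1) under the null even for the
heavily discrete statistics small networks produce (a deterministic
conservative variant is reported alongside).

*Reference-bound manipulation* scales or sets the historical bounds of
chosen internal reactions (exempt classes refuse edits) and the
coupling experiment iterates this over random reaction groups — scale
×10 to *uncouple* (variation turns cryptic), ×0.5 to *couple* (new
reactions become limiting); the defaults are configurable since only
the direction of the manipulation, not its magnitude, is canonical.

## Synthetic scenarios and what they do (not) show

The toy generator builds linear chains and branched multi-precursor
networks with per-reaction reference *slack* factors: slack 1 plants a
growth-limiting gene, slack > 1 plants cryptic variation. Toy biomass
yield is normalized to 1 so growth equals the limiting flux and every
scenario carries a closed-form min-type growth function; fixtures
verify analytic = LP to 10⁻⁸ at construction and dataset time. The
family covers isozyme (OR) and complex (AND) rules, reversible steps,
exempt classes, shared-upstream pleiotropy and multi-substrate media.
These fixtures imitate the structural mechanisms of genome-scale
models — min-form flux limitation, rule redundancy, historical slack —
not yeast biochemistry: passing tests demonstrate the machinery's
correctness and the qualitative phenomena (sparse predictor sets,
cryptic variation, portability collapse, the genetic-variation
trade-off), not quantitative yeast numbers, which require the iND750
reconstruction (`scripts/reproduce_yeast.py`).

Choices of scale in the shipped tests and experiments (populations of
a few hundred, ensembles of tens of media, Sobol bases of 2¹³–2¹⁶,
10-point log-spaced σ grids from 0.01 to 0.5) are the package's
defaults for desk-scale work; all are parameters. The cryptic-slack
demonstration samples at σ = 0.2 because at σ = 0.1 a slack-2 network
yields an exactly constant phenotype (the degenerate-fit path), while
σ = 0.2 leaves a trace of variance with all of it still cryptic at the
dosages the population actually visits.

## Known limitations

- Dosages act on flux *bounds* only; there is no kinetic or
  proteome-allocation layer, no knockout-specific methods (MOMA/ROOM),
  no FVA or loopless correction.
- The random-media inclusion scheme and the reference-ensemble
  rebounding follow one of several defensible readings (per-medium
  inclusion probability; negated-draw reversible lower bounds); both
  are isolated behind single functions and recorded in provenance.
- Populations are in exact linkage equilibrium; there is no genealogy,
  selection, or allele-frequency structure.
- GRR evaluation treats dosage as the sole determinant of capacity;
  regulatory interactions between genes are outside the map.
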