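# Methods

This note documents the models and procedures implemented in `yieldpath`,
the choices made where several defensible options existed, and what the
synthetic study does and does not establish about real field data.

## Scope and data flow

The pipeline decomposes soybean grain yield (GY) into the three classical
efficiencies — light-interception efficiency (Ei), radiation-use
efficiency (RUE) and harvest index (HI) — and places them in a network of
14 physiological and phenological traits measured on a maturity-controlled
panel of recombinant inbred lines (RILs) grown in three environments:

    plot observations ──► per-plot traits ──► per-environment BLUEs
        (canopy, biomass, phenology,          (spatially adjusted
         gas exchange, light, yield)           mixed model, standardized)
                                                      │
                 ┌────────────────────────────────────┤
                 ▼                                    ▼
      kinship multitrait REML              replication/block-corrected
        G, R, genetic correlations,            plot phenotypes
        heritabilities                                │
                 │                                    ▼
     ┌───────────┼───────────────┐        Finlay–Wilkinson joint regression,
     ▼           ▼               ▼          stability typing, Kendall τ
  path analysis  LASSO network  cross-env τ

Every box is a library function under `src/yieldpath/`; the numbered
scripts under `analysis/` drive the chain on the synthetic study and write
their tables under `results/study/`.

## Canopy dynamics

Canopy coverage y(t) (% of plot area) over days after planting (DAP)
follows the three-parameter logistic

    y(t) = k·y0 / (y0 + (k − y0)·exp(−μmax·t)),

with y0 the initial coverage (%), k the maximum coverage (≤ 100%), and
μmax the maximum relative growth rate (1/day). Fitting is nonlinear least
squares (trust-region reflective) with multi-start initialization
(y0 = min observed clamped to ≥ 0.1, k = max observed clamped to ≤ 100,
μmax ∈ {0.05, 0.1, 0.2}) and bounds 0 < y0 ≤ k ≤ 100, 0 ≤ μmax ≤ 1. Fits
that fail from every start are returned flagged and excluded from
downstream trait tables rather than raised, mirroring how aberrant plots
are discarded in practice.

Derived quantities:

* **AGR40** — mean of the analytic derivative dy/dt on the integer grid
  t = 1..40 DAP (%/day). The exact integral mean, (y(40) − y(0))/40, is
  available via `agr40(..., integral=True)`; the two differ by < 5% for
  realistic parameters. The grid mean is not strictly monotone in μmax at
  extreme values (μmax ≳ 0.3, where the curve saturates within days); over
  the agronomically relevant range (≤ 0.3/day) it is.
* **Intercepted PAR** — daily incident PAR = `par_fraction` × global solar
  radiation (default 0.5; the fraction is nowhere standardized tightly,
  0.45–0.50 being the common range), intercepted share = y(t)/100.
* **Ei** — Σ intercepted / Σ incident over the window planting (DAP 0)
  through each plot's R8 (full maturity). An emergence-to-R8 window is a
  config option (`interception_window`); the planting-based default is the
  physiologically coherent reading of "total PAR available for the
  season". Ei is invariant to any uniform rescaling of radiation.

## Physiological traits

* **RUE (slope)** — OLS slope of aboveground dry matter (g/m²) on
  cumulative intercepted PAR (MJ/m²) across the season's biomass
  samplings, with a freely estimated intercept: samplings start around
  38 DAP, so forcing the line through the origin would bias the slope when
  early growth deviates from proportionality (an origin-forced option
  exists). Used in the environments with three samplings.
* **RUE (ratio)** — total dry matter over cumulative intercepted PAR, for
  the environment with a single late-season sampling.
* **HI** — seed weight at 0% moisture over total aboveground dry matter.
  Grain yield is carried separately at 13% moisture (kg/ha); the two
  moisture bases are never mixed.
* **K** — Beer–Lambert extinction coefficient from a single light pair at
  maximum canopy: K = ln(I0/I)/LAI.
* **RL = R8 − R1, SFL = R7 − R5** (days). R7 is treated as an observed
  input: the stage-scoring protocol lists R1, R5 and R8, yet the
  seed-filling interval is defined through R7; how R7 was obtained in the
  field is not documented, so the pipeline accepts it as data and the
  generator emits it.
* **Biomass adjustment** — per sampling date, dry matter is regressed on
  RIL, environment and replication factors plus plant count, and each plot
  is moved to the grand-mean plant count (fitted-plus-residual). Factors
  that would make the design rank-deficient are dropped with a warning;
  if the plant count itself is confounded with the retained factors the
  adjustment refuses rather than silently attributing genetic differences
  to the covariate.

## Stage-one mixed model

Per trait and environment,

    Y_ijk = μ + f(x) + α_i + (αβ)_ij + δ_k + e_ijk,

with fixed intercept, fixed nearest-neighbour covariate f(x) (mean of the
phenotypes of the four rook-adjacent plots; edge plots use the 1–3
available neighbours, never diagonals; an isolated plot receives the field
mean with a warning), fixed RIL effects δ (sum-to-zero contrasts), and
random replication, replication-by-block and residual terms. The covariate
uses raw neighbour phenotypes, not residuals; no iteration. A constant
covariate (uniform field) is dropped as collinear with the intercept.

REML profiles the residual variance and optimizes the two variance ratios
by Nelder–Mead on the restricted log-likelihood from three starts; with
q ≈ 66 random-effect levels all matrix work runs through the Woodbury
identity on cached cross-products, so cost is dominated by one Cholesky of
the p × p fixed-effects information per evaluation. Variance components
estimated at the zero boundary are kept, with a warning. BLUEs are
reported as intercept + δ_k; the contrast convention only shifts BLUEs by
a constant, which the per-environment z-scoring (sample SD, n − 1) removes.

For the joint-regression input, plot values are corrected by replication
and incomplete block only (fixed-effect OLS adjustment, no spatial
covariate, genetic effects left in the data).

## Kinship and the multitrait model

Kinship is VanRaden's first method on 0/1/2 dosages; monomorphic markers
are excluded from the scaling. For the inbred panel the diagonal sits near
2 (1 + F with F ≈ 1).

G (additive-genetic) and R (residual) trait covariance matrices come from
kinship mixed models on the per-line means of the standardized
cross-environment BLUEs — the entry-mean basis, which is also the basis on
which the heritabilities h² = G_ii/(G_ii + R_ii) are reported. Averaging
over environments makes R absorb environmental and genotype-by-environment
covariance along with measurement error; h² on this basis is accordingly
higher than plot-level h². Rotating each trait vector by the eigenvectors
of the kinship matrix makes lines independent with per-line variance
d_i·G + R, so:

1. univariate REML per trait — the variance ratio is profiled on a log
   grid plus bounded refinement;
2. bivariate REML per trait pair for the two covariances, with the
   variances fixed at their univariate estimates and the two correlations
   parameterized through atanh (Nelder–Mead with restarts);
3. assembly and PSD bending — eigenvalues clipped at 1e-6, rows/columns
   rescaled to preserve the diagonal, and the spectral norm of the
   perturbation reported on the fit object.

A 14-trait unstructured joint REML would have 210 parameters and is
numerically fragile; the pairwise scheme with PSD repair is standard
practice and is validated by recovery simulations rather than by matching
any published matrix. A trait whose genetic variance lands on the zero
boundary (h² < 0.02) has no defined genetic correlation; such entries are
returned missing. `run_pipeline` imputes them as 0 (logged) for the matrix
analyses while the saved correlation table keeps them missing.

Statistical limits worth knowing: with a family-structured panel the
effective units behind a genetic correlation are closer to the number of
families than the number of lines. At 32 families the per-pair sampling
SD is ≈ 0.13 even for data generated exactly under the model, so
single-seed recovery checks assert the median error across pairs and sign
agreement for strong correlations rather than a uniform per-pair bound.

## Path analysis

Standardized path coefficients solve R_XX·b = r_Xy per endogenous
variable — per-equation OLS on the correlation matrix, equivalent to a
recursive structural equation model with uncorrelated residuals. No
latent variables, fit indices, or coefficient standard errors are
produced. Indirect effects follow directed chains only: the indirect
effect of s on t is the sum over all directed paths of length ≥ 2 of the
products of coefficients along each path; total = direct + indirect.
Coefficients are reported signed at full precision (summaries round to 2
decimals). `implied_correlation_check` reconstructs r_vy = Σ_j b_j·r_vj
for every variable v — exact for parents by the normal equations,
diagnostic for omitted predictors otherwise.

The default diagram encodes the predictor sets enumerable from the study's
results narrative — Ei ← {AGR40, R1, K}; K ← {AGR40, LAI}; RUE ← {R5,
iWUE, RL, K, A, LAI, AGR40}; HI ← {A, SFL, AGR40, RL, R5}; GY ← {HI, RUE,
Ei, R1} — and ships as data a user can override with any acyclic diagram:
the published figure may contain arrows not recoverable from text.

On the published matrix this reproduces the printed coefficients to within
±0.05 for every reported entry except the R5 coefficient of the RUE
equation (computed 0.66 vs printed 0.73); the inputs are printed to two
decimals only, and no predictor-set variant consistent with the text
reconciles that single entry without breaking others.

## Undirected network

Neighborhood selection: each trait is lasso-regressed on all others
directly on the correlation matrix by cyclic coordinate descent
(b_k ← soft-threshold(r_kj − Σ_{m≠k} r_km·b_m, λ); zero start, fixed
sweep order, tolerance 1e-8, ≤ 10,000 sweeps — bit-reproducible). Edges
combine neighborhoods with the OR rule by default (AND available). A
non-PSD input is bent with a warning.

The penalty is chosen by extended BIC (γ = 0.5) on the nodewise Gaussian
pseudo-likelihood, Σ_j [n·log(rss_j) + k_j·log n + 2γ·k_j·log(p−1)], over
a 30-point logarithmic grid from λ_max (empty graph) down to 0.01·λ_max,
with n the effective sample size (the line count). On correlation matrices
implied by sparse well-conditioned precision matrices this recovers the
true edge set essentially perfectly (median F1 = 1.0 at p = 14, 15 edges,
n = 350). On the published 14-trait matrix, whose correlations are strong
and which is indefinite at 2-decimal rounding, EBIC at n = 383 prefers
dense graphs; the analysis script therefore also reports the sparse graph
at a comparable edge count to the published figure, whose exact penalty is
unknown. Note that lasso solution paths are not monotone for correlated
predictors: neighborhoods can lose members as λ decreases (observed on the
published matrix); monotonicity holds only in the orthogonal case.

## Stability

The Finlay–Wilkinson joint regression y_ij = μ + g_i + (1 + b_i)·h_j +
e_ij is fitted by alternating least squares: given slopes, h is the
slope-weighted regression of environment deviations; given h, per-line OLS
gives (g_i, b_i); the constraints Σg = Σb = Σh = 0 (mean slope exactly 1)
are applied every iteration, and iteration stops when the relative RSS
change falls below 1e-10. With an identity relationship among lines this
least-squares fit coincides with the posterior mode of the common Bayesian
formulation under flat priors, which is why a sampler is not needed; the
substitution is validated by slope-recovery simulations. Lines missing any
environment are dropped. When the environment-index range is small
relative to the residual scale the fit warns that slopes are poorly
determined — with near-identical environments the slope is a noise ratio
(harvest index, which varies little across environments, is the
pipeline's own example).

Typing: slope > 1.5 → type III (favorable-environment responders),
slope < 0.5 → type IV, |slope − 1| ≤ 0.25 (configurable) → type II;
the remainder unclassified. IQR uses linear (type-7) quantiles.

Kendall's τ is the τ-a form — (concordant − discordant)/(n(n−1)/2), ties
counting toward neither — matching the definition used for the
cross-environment rank correlations; τ-b would rescale for ties and is not
what the formula states. Cross-environment matrices use the intersection
of lines per environment pair.

## The synthetic study

The generator exists to give every stage a parameter-recovery test with
known truth; its defaults emulate the real study's structure: 383 RILs
from 32 biparental families, 3,000 biallelic SNPs (scaled down from the
study's 23k — kinship estimates stabilize well below that), three
environments in an alpha-lattice design with 2 replications × 32
incomplete blocks, ~4% of plots discarded, six canopy-coverage flights at
~12-day intervals, three biomass samplings (38/58/84 DAP) in two
environments and one (91 DAP) in the third, and seasonal incident solar
radiation near 2,000 MJ/m².

* **Genotypes** — two founder haplotypes per family at allele frequency
  0.5; each RIL inherits one founder allele per marker independently (no
  linkage map) with 2% residual heterozygosity; monomorphic markers are
  redrawn.
* **Breeding values** — marker effects drawn i.i.d. and linearly
  recombined so the across-line sample covariance of the 12 latent traits
  (μmax, maximum coverage, RUE, HI, R1, R5, R7, R8, LAI, K, A, iWUE)
  equals the target G exactly while remaining additive in dosages. The
  default G is seeded from the published additive-genetic correlations
  where a latent maps to a published trait, with mild invented values for
  the two latents without an analogue, bent to PSD; heritabilities follow
  the published diagonal. Latent means and SDs are calibrated so the
  emitted per-environment trait means fall within the published ranges.
* **Environments** — per-trait mean shifts per environment (later
  phenology and slower early growth in the 2018-like environments, etc.)
  plus a yield-potential index η = (−0.16, +0.06, +0.10): plot biomass is
  multiplied by 1 + slope_i·η_e, with per-line sensitivities slope_i
  averaging exactly 1 — the Finlay–Wilkinson generative form, so the
  average line follows the common environment response.
* **Field effects** — a smooth standardized spatial surface (low-order
  polynomial + smoothed noise) loading on each trait with trait-specific
  coefficients, plus block and replication effects independent across
  traits. An earlier design that loaded one shared field effect on all
  traits equally produced residual trait correlations near 1 and genuinely
  confounded the genetic/residual covariance split; the loadings keep
  residuals correlated but well-conditioned.
* **Forward model** — canopy from the plot's logistic parameters; biomass
  = RUE × cumulative intercepted PAR × G×E multiplier (plus a plant-count
  covariate effect); grain = HI × final biomass (0% moisture, converted to
  kg/ha at 13%); light pair from Beer–Lambert at the measured LAI;
  phenology rounded to integer days with ordering enforced. Measurement
  noise per channel is a config block (`NoiseConfig`); the canopy-coverage
  error is plain additive Gaussian (σ = 2% coverage) because the
  acquisition chain's error structure is not documented — it is a knob,
  not an assertion.

What passing recovery tests establish: the estimators are consistent under
the generative model at the study's scale — genetic correlations track the
generating values (median |error| ≈ 0.08 at 383 lines), heritability ranks
are preserved, FW slopes recover designed sensitivities at the documented
noise level, and the graphical model recovers sparse structure from exact
correlation input. What they do not establish: robustness to non-Gaussian
measurement error, spatial structure beyond smooth trends, linkage and
selection in real RIL genomes, assimilate-dynamics realism (biomass is
strictly proportional to intercepted light within a season), or the
behaviour of FW slopes when real G×E deviates from the multiplicative
form. On the full mechanistic panel the measured grain-yield FW slopes
correlate ≈ 0.7–0.8 with the designed sensitivities even though estimation
is exact on clean FW data, because measured slopes also absorb line-mean
scale effects and phenology-by-season interactions — a property real
joint-regression analyses share.

## Problem sizes and determinism

The analysis scripts run the full 383-line panel (≈ 2,200 plots; the whole
chain completes in minutes). The test suite exercises the same code on
120–400-line panels, chosen as the smallest sizes at which the recovery
properties it asserts are statistically meaningful. All randomness flows
through `numpy.random.default_rng` seeded per stage from a single integer;
identical configuration and seed reproduce every CSV byte-for-byte.
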