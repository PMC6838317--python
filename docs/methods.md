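# Methods

This note documents the models implemented in `subsidydiet`, the choices
made where the design was genuinely open, what the synthetic-data generators
do and do not emulate, and the known limitations of each stage.

## Fecal contribution statistic

Scats are tabulated as FO (percent of scats containing an item at least
once; a scat counts once however many matching items it holds) and NI
(minimum individuals, from diagnostic bones). The contribution of taxon *t*
to the predators' energy budget is

    contribution_t = 100 · (W_t · NI_t / n) / mean DCB   (%)

where `n` is the number of scats, one defecation per cat-day is assumed, and
DCB (daily consumed biomass, g wet prey/day) comes from the eutherian
allometry `DCB = 3.358 · W^0.813 · 2.86/18` with predator weight W in grams
(2.86 rescales dry mass for 65% prey water content; 18 kJ/g dry energy
density). Mean DCB averages per-cat DCB values, not the DCB of the mean
weight — the power is concave, so the two differ for heterogeneous weights.
Prey heavier than the maximum DCB are capped at it: a cat abandons what it
cannot eat in a day, so a 2.9 kg rabbit enters the statistic at the heaviest
cat's daily intake (629 g), not at its own body mass.

Numerical conventions:

* Weights are stored internally in grams; cat records accept kilograms and
  convert on ingest.
* All comparisons and subtotals use unrounded values; display rounds
  half-up to one decimal. Printed *integer* DCB values are truncated (not
  rounded) to whole grams — the published range endpoints (146 and 629 g)
  are floor values of 146.6 and 629.2.
* Taxa with no usable body weight (pooled insect groups, artificial
  objects, plants) are tabulated for FO/NI but excluded from contributions.
* The warbler *Horornis diphone* uses both forest and village habitat and
  is categorised "unknown" in the shipped taxon table; the assignment lives
  in the table, not in code.
* Source selection keeps taxa with contribution strictly above the
  threshold (default 3%).
* Fisher's exact test between groups is two-sided by probability-mass
  ordering (`scipy.stats.fisher_exact`); a brute-force hypergeometric
  enumeration oracle backs it in the tests.

Known discrepancy: the published forest-category subtotal (15.5%) cannot be
regenerated from the published per-taxon weights and NI, which sum to
~16.0% unrounded; every individual taxon value *is* reproduced exactly.
The package reports the computed subtotal.

## TEF estimation

Sheltered cats switched to a single known diet approach the tissue–diet
equilibrium as hair turns over; the offset series Δδ(t) is fitted with the
asymptotic exponential `A·e^{B·t} + C` by nonlinear least squares, and the
TEF is the asymptote C. Choices:

* Initialisation: C₀ = mean of the latest tercile of observations,
  A₀ = first observation − C₀, B₀ = −ln 2 / median(day). Robust for
  monotone approach data.
* B is constrained negative by optimising over log(−B).
* Convergence tolerance 1e-8 on the parameter step, at most 10,000
  residual evaluations; non-convergence is flagged on the estimate, not
  raised, so callers can inspect diagnostics.
* Standard errors are asymptotic (Jacobian at the optimum, delta method
  for B).
* The fit pools observations across cats; per-cat series can be fitted by
  calling `fit_asymptotic` per subset (whether the original analysis pooled
  is not recorded).
* Raw shelter series are not published; the package ships the published
  point estimates (2.3 ± 0.3 ‰ for δ13C, 2.8 ± 0.1 ‰ for δ15N) as
  defaults usable without refitting.

## Bayesian mixing model

For each cat group, diet proportions p over K = 3 sources follow a
Dirichlet(1,…,1) prior, and consumer isotope values follow

    x_ij ~ Normal( Σ_k p_k (μ_jk + c_jk),
                   Σ_k p_k² (ω_jk² + τ_jk²) + σ_j² )

per isotope j ∈ {δ13C, δ15N}, with source signatures μ ± ω, TEFs c ± τ and
residual SDs σ_j ~ Uniform(0, 20 ‰). Source and TEF uncertainty enter
through the marginalized variance term rather than per-consumer latent
draws — the same first two moments with a far simpler sampler; this is a
deliberate approximation of the classic R implementation of this model
family. Groups get independent proportion vectors but share sources and
TEFs; each group is fitted in its own chain.

Sampler: random-walk Metropolis on the additive log-ratio transform of p
(softmax with the last coordinate fixed; the Dirichlet-prior Jacobian
Σ log p_k is included) jointly with log σ. The additive rather than
centered log-ratio chart is used because it is full-rank; the induced
posterior is identical. The proposal scale adapts every 200 iterations
during burn-in toward ~30% acceptance and is frozen afterwards. The default
schedule is 50,000 iterations, 5,000 burn-in, thinning 10, explicit seed.
Diagnostics: post-burn-in acceptance rate and autocorrelation-based
effective sample size per component; zero acceptance raises. Correctness
was cross-checked against an independent MCMC of the identical model (and,
in the vanishing-variance limit, against the algebraic solution of the two
isotope balances plus closure).

HDR summaries are shortest contiguous intervals containing ⌈mass·N⌉ sorted
draws (default mass 0.95).

Reproduction caveat: regenerating consumers from the published group
means/SDs and running this model gives feral dependence ≈ 71% artificial /
17% forest / 12% farmland against the published 67.8 / 14.3 / 17.9. The
published fit used an R package whose exact version and prior settings are
not recorded; an independent sampler run on the same inputs reproduces our
values, so the residual few-point gap reflects that unrecorded
configuration (and the fact that only rounded summary statistics of the
real consumers survive), not sampler error. Indoor cats (n = 9) are
excluded from mixing by default, matching the published group comparison.

One-way ANOVA and Tukey HSD group comparisons delegate to
scipy/statsmodels-grade routines (`f_oneway`, `tukey_hsd`).

## Landscape GLMs

Per-cat dependence proportions are arcsine-square-root transformed
(`asin(√p)`, the classical variance stabiliser for proportions) and
regressed on landscape structure:

* **Buffer covariates** — coverage of forest, residential and farmland
  classes plus building density (points/km²) in 100/200/500 m radius discs.
  Polygon layers use exact shapely intersection areas; gridded layers count
  cell centres. The factor analysis uses the 500 m set by default (the
  feral/stray field distinction is drawn at 500 m from villages); the
  radius is configurable, as the original choice is not recorded.
* **Factor analysis** — maximum-likelihood extraction (scikit-learn's EM
  factor model on standardized covariates), two factors as suggested by
  parallel analysis (observed correlation eigenvalues vs. means over 100
  random-normal datasets), Promax rotation with power 4 (the conventional
  default), Thurstone regression factor scores. Factors are sign-oriented
  so the dominant variable loads positively.
* **Moran's eigenvector maps** — binary adjacency from Delaunay
  triangulation (chain-graph fallback for collinear sites; duplicate
  coordinates error unless a jitter is configured), double-centered and
  eigendecomposed; eigenvalue-descending eigenvectors become MEM1, MEM2, …
  with the first non-zero loading positive, making scores bit-for-bit
  reproducible. MEM selection tests MEM1…MEM10 one at a time by OLS t-test
  against each response at α = 0.05 and keeps MEM1…MEM_J for the largest
  significant J — the simplest defensible reading of "largest significant
  MEM"; the test lives behind one function so a permutation Moran's I can
  be swapped in.
* **Model averaging** — all 2^t subsets of the candidate terms (factors,
  weight, sex, retained MEMs) fitted by OLS; AICc
  `n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with k counting intercept, slopes
  and the variance; the ΔAICc < 2 set is averaged with renormalized Akaike
  weights using *full* averaging (a term absent from a model contributes 0,
  the default of the standard multimodel-inference package) and adjusted
  SEs combining within-model variance and between-model spread; z and
  two-sided normal p follow, with the usual significance stars.

Per-cat dependence values are an open modelling question upstream: the
published mixing model was fitted per group, yet the landscape model needs
individual responses. The pipeline treats per-individual dependence values
(however obtained — per-individual mixing fits or posterior draws) as its
input and documents the ambiguity rather than resolving it silently. The
published note that residential-area dependence correlates with forest
coverage is internally inconsistent with the sign table and is most likely
a transcription slip for forest-animal dependence; the package does not
"correct" anything, it simply fits what it is given.

## Synthetic data

All generators are pure functions of (config, seed). The shipped
island-calibrated scenario sets every truth to a published summary:

* **Fecal tables** — per-taxon, per-group occurrence Bernoulli at the
  published FO rates; counts conditional on occurrence are shifted-Poisson
  with the rate set from the published NI/occurrence ratio (NI rarely
  exceeds the scat count by much). A deterministic variant
  (`table1_fixture`) packs occurrences cyclically so per-taxon scat counts,
  per-category distinct-scat counts (e.g. forest items in exactly 35 of 174
  feral scats) and NI match the printed table exactly.
* **Cat weights** — truncated normal on 1.0–6.0 kg (SD 1.0 kg) with the
  location root-found so the per-cat mean DCB equals the published 379 g
  (the original weight list is unpublished; the published mean DCB implies
  per-individual averaging).
* **Consumers** — `empirical` mode draws from the published group
  means/SDs and, by default, standardizes each group's sample moments to
  them exactly: the mixing likelihood depends on the data only through
  per-isotope sample moments, so this reproduces the original inference
  inputs without seed jitter. `mixture` mode forward-simulates from the
  mixing model at configured true proportions for recovery tests.
* **Shelter series** — `A·e^{B·t} + C` plus Gaussian noise at integer days
  in the published 23–536-day stay range; defaults use the published
  asymptotes with noise scaled to the published TEF standard errors.
* **Landscape** — a smoothed Gaussian random field thresholded at the
  quantiles of the configured class shares (defaults 43% forest, 28%
  farmland, 8% residential, 21% other cover, so the modelled coverages do
  not close to one), Poisson building points on residential cells, capture
  sites uniform over interior cells with sub-cell jitter.

What the generators do **not** emulate: cat movement and home ranges,
spatial clustering of captures around trap lines, diet–landscape coupling
beyond user-specified linear effects, digestibility differences between
prey, isotope covariance between δ13C and δ15N within individuals, and
seasonal variation. Passing recovery tests therefore demonstrates that the
estimators are correct under the stated models at realistic magnitudes, not
that the models capture every feature of field data.

## Problem sizes and runtime choices

Default test and pipeline sizes are chosen to exercise the statistics at
the study's own scale where that is cheap (189 + 52 consumers, 50,000 MCMC
iterations, 198 scats, 165 sites) and at reduced scale where replication
matters: the simulation-based-calibration suite runs 200 simulate→fit
cycles at a 5,000/500/5 schedule with 30 consumers per cycle, and TEF
recovery uses 200 replicates of 30-point series. HDR coverage at the
reduced schedule was verified to sit within 1 point of nominal, so the
shorter chains do not distort the calibration check.

## Known limitations

* The mixing model ignores concentration dependence and isotopic routing
  and supports exactly the marginalized-variance likelihood above; >2
  isotopes or covariate-structured proportions are out of scope.
* The factor-extraction step relies on an EM fit of the ML factor model;
  degenerate (non-positive-definite) correlation matrices are rejected
  with a condition-number diagnostic.
* Geographic coordinates must arrive as planar meters; no projection
  handling is performed.
* Group-level TEFs are assumed diet-independent; the diet-switch design
  only identifies them for the pet-food diet.
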