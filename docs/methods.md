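# Methods

## Scope

`multidiv` implements a complete desk-scale replica of a multidimensional
biodiversity analysis: survey preparation (block aggregation,
trait-completeness filtering), per-unit diversity metrics, a latent-variable
structural equation model (SEM) fitted by maximum likelihood, and the
classical ANOVA/MANOVA/stepwise baselines — plus a synthetic-data generator
that stands in for the un-deposited field survey. Everything downstream of
the generator treats its output exactly as it would treat real files
(tidy CSV, Newick).

## Survey preparation

A quadrat-level community matrix holds one record per (block, plot, fence,
quadrat, species) with percent cover; species absent from a quadrat are
zeros, not missing. Aggregation averages the 10 quadrats within each
plot × fence unit (absences contributing 0), so the 240-quadrat design
collapses to 24 replicate units; "block" is operationalized as plot × fence,
the only reading that yields 24 units from 12 plots. The trait filter drops
species with any missing trait value and reports the fraction of total
summed cover retained. Species identifiers are normalized
(whitespace → underscores) before matching the trait table and tree.

## Diversity metrics

Per sample unit: richness S, Shannon entropy in nats, Gini–Simpson
1 − Σp² (an inverse-Simpson variant is available by flag), FEve, FDiv, FRic,
Faith's PD and abundance-weighted MPD, plus summed total cover. Abundances
are relative covers within the unit.

Functional indices live in a common trait space: each trait is z-scored
over the *full filtered species pool*, not per unit, so hull volumes and
distances are comparable across units (per-unit standardization would make
FRic incomparable; the alternative is deliberately not implemented). The
MST uses a lexicographic tie-break (an infinitesimal, order-dependent
perturbation far below data scale) so results are reproducible when
distances tie. Convex hulls collapse to the spanned subspace when a
community is degenerate in one or more trait dimensions; FRic then carries
that subspace's dimensionality, and a fully coincident community yields an
undefined metric, recorded as missing with a reason — never as 0. FEve is
undefined below three species; MPD below two species with positive
abundance.

Faith's PD includes the stem path from the spanning subtree down to the
supplied tree's root (the classic Phylocom convention); a no-root variant is
available by flag. MPD uses distinct pairs i<j only, in both numerator and
denominator.

One property worth stating honestly: FEve and FDiv are *designed* to be
independent of richness, and over random communities whose richness and
abundances are drawn independently the rank correlation with S is ≈ 0 (this
is tested). In aggregated survey data, however, rich units carry many
near-trace species (a species present in 1 of 10 quadrats at 0.1% has unit
mean cover 0.01%), and FEve genuinely declines with the number of such
species — a property of the data-generating process, not of the index.
Single-survey correlations as strong as −0.8 can appear at 24 units.

## The latent-variable engine

RAM parametrization over stacked observed + latent variables: directed
paths in A, exogenous variances/covariances and disturbances in Ψ,
Σ_all = (I−A)⁻¹Ψ(I−A)⁻ᵀ. Models are declared programmatically or as plain
text (`A -> B`, `A <-> B`, `fix A -> B @ 1`, `latent F`); every variable
automatically gets a free variance term unless one is declared. Latents are
scaled to unit variance rather than by marker indicators, so all loadings
are free and latent covariances are correlations — the convention under
which reported covariance estimates coincide with their standardized
values.

Fitting minimizes the Wishart discrepancy F_ML with an analytic gradient
(dF = tr[W dΣ], W = Σ⁻¹ − Σ⁻¹SΣ⁻¹, with path and covariance derivatives
reduced to entries of two precomputed matrix products). Numerical choices
that matter:

- **Internal rescaling.** The optimizer works on the unit-variance
  rescaling of S (F_ML is invariant under diagonal rescaling) and maps
  estimates/SEs back through the exact linear factors. This keeps the
  problem conditioned when observed variances span orders of magnitude
  (total cover vs Simpson), and makes the start values — paths 0.5,
  observed variances at the sample variance (≡ 1 after rescaling), latent
  variances 1, covariances 0 — scale-free.
- **Positive-definiteness barrier.** Outside the PD region the objective
  becomes a penalty on the smallest eigenvalue of Σ with a consistent
  gradient (W = −c·vvᵀ), so the optimizer walks back in instead of
  stalling.
- **Optimization schedule.** BFGS (max 300 iterations), then a Newton-CG
  polish with finite-difference Hessian-vector products when the gradient
  is small but above tolerance, then a final gradient-norm refinement
  (Newton steps solved by conjugate gradients) — near the optimum F itself
  bottoms out at double-precision noise while the analytic gradient still
  carries signal, and this step resolves e.g. the saturated-model identity
  Σ(θ̂) = S to ~1e−15. Convergence is declared at gradient sup-norm < 1e−6.
  On failure, up to 20 jittered restarts alternate between perturbing the
  start and perturbing the best point found; restarts stop early after six
  non-improving attempts or when a parameter runs away on the standardized
  scale (|θ| > 50).
- **Unbounded likelihoods.** At N = 12 on the case-study model the ML
  function is, for many datasets, genuinely unbounded: a loading diverges
  with a compensating negative error variance (the severe Heywood
  direction). No optimizer converges there; the engine returns a flagged
  fit with diagnostics (best gradient norm, restart count, runaway note)
  rather than failing silently or pretending convergence. No bound
  constraints are imposed anywhere: negative error variances and
  standardized coefficients beyond ±1 are reported as estimated and
  flagged.

Standard errors come from the inverse Hessian of F_ML (finite differences
at θ̂) scaled by 2/(N−1); critical ratios are estimate/SE with two-sided
normal p-values. Standardization divides by implied standard deviations
from Σ_all(θ̂); relations touching a variable with non-positive implied
variance standardize to NaN and raise a flag. R² for an endogenous variable
is 1 − ψ_vv/Σ_all[v,v]. RMSEA uses the N−1 convention throughout, and the
close-fit probability is the upper tail of the observed χ² under a
noncentral χ² with noncentrality (N−1)·df·0.05² (H₀: RMSEA ≤ 0.05; the
reference value is conventional). `min_sample_size` is the
10-observations-per-free-parameter rule of thumb.

The case-study model has three latents with two indicators each, three
structural paths into Total_Cover, three latent covariances and (in the
default *covariate* variant) three nTaxa covariances: 15 structural
relations plus 8 variance terms = 23 free parameters, df = 36 − 23 = 13.
*indicator* and *omitted* variants move or drop nTaxa.

## Classical battery

One-way ANOVA per metric (scipy behind the surface). MANOVA is computed
directly from the between/within cross-product matrices H and E because the
contract includes standardized canonical coefficients (leading eigenvector
of E⁻¹H scaled by error SDs, first nonzero entry positive) and Roy's
upper-bound F, which library implementations do not expose; the statistics
and F approximations (Rao's F for Wilks, the standard trace approximations,
Roy's bound) are cross-checked against statsmodels in the tests. Backward
stepwise regression repeatedly drops the predictor with the largest
p-value while it exceeds α (default 0.05), dropping aliased columns first
with a warning; an AIC criterion is out of scope. A caution the validation
quantifies: with five null candidates at n = 12 this procedure falsely
retains a nuisance term in roughly a quarter of runs at α = 0.05, so the
single-predictor recovery experiment uses a Bonferroni-style removal
threshold (0.01/5).

## Synthetic data

The generator's defaults mirror the study design: 12 plots × (fenced +
unfenced) × 10 quadrats = 240 surveys; a 45-species pool of which the 31
most abundant carry complete traits (masking removes one random trait from
the `missing_trait_fraction` = 0.31 lowest-cover species), so the trait
filter retains ≫85% of cover; cover recorded to the nearest 1% with true
covers in (0, 0.5%) recorded as the trace value 0.1%.

Trees are pure-birth (Yule): exponential waiting times with rate k between
the k-th and (k+1)-th birth, a final waiting interval, all tips extant —
hence ultrametric with strictly positive branch lengths. Traits evolve by
Brownian motion from root value 0, independently per trait (correlated
traits are a non-goal), so tip covariance is σ² times shared root-path
length — the property the tests verify against path enumeration. Note the
resulting trait values are centred at 0 and can be negative; empirical
leaf traits are positive, and an opt-in positivity check exists on the
reader, but the functional-diversity machinery only ever uses z-scores.

Species base covers are log-normal (meanlog 0, sdlog 1.2, percent scale);
plots rescale them by a log-normal effect (sd 1.0) and include each species
with probability b/(b+1) (species turnover across plots — the source of
richness variation between units); quadrats within an occupied plot carry
the species with probability 0.7 and log-normal noise (sd 0.5). These
knobs were set once to give ~15–30 species and realistic cover per unit;
they are stand-ins, not calibrated field claims. Herbivory multiplies the
cover of palatable species — the top SLA tercile, a standard
leaf-economics proxy for browsing preference — by (1 − effect), default
effect 0.5, in unfenced quadrats only. Quadrat noise and occupancy are
drawn once per plot and shared between the paired fenced/unfenced halves,
so a zero effect produces literally identical paired communities (the null
contract several tests use). Herbivory therefore reduces cover and
abundance-weighted metrics but not richness; a generator in which deer
remove species outright is future work.

Each operation draws from its own RNG stream (`seed` plus a stable
per-operation tag), so trees, traits and landscapes can be regenerated
independently and all outputs are byte-identical under a fixed seed.

What passing tests on this generator do *not* show: real surveys have
observer error, spatial autocorrelation, interannual dynamics, correlated
trait evolution and phylogenetic signal in palatability, none of which are
modelled. The generator's role is to exercise the pipeline's contracts with
known ground truth, not to imitate a particular forest.

## Validation experiments

`scripts/acceptance.py` (and the mirror tests) recompute: agreement of all
seven diversity metrics with independent brute-force oracles (exhaustive or
union-find MSTs, LP-based hull membership, Delaunay-determinant volumes,
root-path phylogenetic distances) on 200 random communities; SEM parameter
recovery on data simulated from the case-study model at n = 5000 × 100
replicates (every parameter within 3 SE ≥95% of the time, mean RMSEA of the
true model < 0.05); the saturated-model identity; MANOVA's exact
degeneracy to ANOVA at q = 1 and the Wilks test's type-I error over 2000
null simulations; stepwise single-predictor recovery; the design
aggregation counts and the sample-size rule; and cross-engine agreement of
ML estimates with an in-repo independent reference (implied covariance by
path enumeration over the model graph, derivative-free/finite-difference
minimization) to well under 1e−4 relative on 20 random factor models. The
problem sizes above were chosen to make each experiment statistically
decisive at desk scale.

## Known limitations

- Mean structures, multi-group invariance, missing-data FIML, Bayesian
  estimation and fit indices beyond χ²/RMSEA are out of scope.
- The two-indicator-per-latent design is only just identified through the
  inter-latent covariances; datasets in which those covariances are near
  zero (or N is tiny) produce unbounded likelihoods, reported as flagged
  non-convergence.
- SES-style null-model metrics (SES-MPD, Rao's Q, Hill numbers) are not
  implemented.
- The generator's herbivory acts on cover only; treatment effects on
  richness/PD arise only indirectly.
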