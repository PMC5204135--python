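# multidiv

Multidimensional biodiversity analysis for plot-based vegetation surveys:
compute taxonomic, functional and phylogenetic diversity metrics from
plot × species percent-cover data, a species × trait table and a phylogeny,
then quantify how the *dimensions* of biodiversity jointly influence an
ecosystem property (total understory cover) with a latent-variable
structural equation model, contrasted against the classical
ANOVA / MANOVA / stepwise-regression battery.

The motivating setting is a blocked deer-exclosure experiment in a temperate
forest understory: 12 plots, each with a fenced and an unfenced half of ten
1 m² quadrats, species cover recorded to the nearest 1% (traces as 0.1%),
leaf traits (SLA, LNC, LPC) for the dominant species, and a dated phylogeny
over the species pool. Because no such survey is publicly deposited, the
package ships a seeded synthetic-data generator that reproduces this design
with known ground truth, so every stage of the pipeline is testable.

## The model

Each *dimension* of biodiversity is an unmeasured latent variable indicated
by two observed metrics:

- **TD** (taxonomic) → Shannon *H* = −Σ pᵢ ln pᵢ and Gini–Simpson
  *D* = 1 − Σ pᵢ²,
- **FD** (functional) → functional divergence and functional evenness in the
  z-standardized (SLA, LNC, LPC) trait space — FEve from the abundance-
  weighted minimum spanning tree, FDiv from abundance placement relative to
  the convex-hull centroid,
- **PD** (phylogenetic) → Faith's PD (branch length of the spanning subtree,
  root included) and abundance-weighted MPD
  (Σ_{i<j} pᵢ pⱼ δᵢⱼ / Σ_{i<j} pᵢ pⱼ with δ the patristic distance).

The three latents (unit variance, pairwise covarying, with species number
nTaxa as a covariate of each) jointly regress Total_Cover. With A the path
matrix and Ψ the exogenous/disturbance covariance (RAM parametrization), the
implied covariance is Σ(θ) = (I−A)⁻¹ Ψ (I−A)⁻ᵀ restricted to the observed
block, fitted by minimizing the Wishart ML discrepancy

F_ML(θ) = ln|Σ(θ)| − ln|S| + tr(S Σ(θ)⁻¹) − p,   χ² = (N−1)·F_ML(θ̂),

with standard errors from the numerically evaluated information matrix,
RMSEA = √(max(χ²−df, 0)/(df(N−1))) with its close-fit probability, and no
bound constraints — inadmissible (Heywood) solutions are reported and
flagged, because at N = 12 per treatment they are part of the story.

Functional richness (convex-hull volume) and raw richness are computed but
deliberately excluded as indicators: both scale with species number.

## Worked example

The numbered scripts under `analysis/` run the whole study; each writes its
tables under `results/`. With the default seed:

```
$ python analysis/01_simulate_survey.py
                               quantity    value
                           species pool  45.0000
           species with complete traits  31.0000
                        quadrat surveys 240.0000
      replicate units after aggregation  24.0000
cover fraction retained by trait filter   0.9859
```

240 quadrat records collapse to 24 replicate plot × fence units, and the
31 trait-complete species hold 98.6% of total cover, so the trait filter
discards almost no information. Then:

```
$ python analysis/02_diversity_profiles.py
24 sample units; trait filter retained 98.6% of total cover

fence        fenced  unfenced
n_taxa       18.583    18.583
shannon       2.293     2.196
total_cover  84.702    75.859
...
```

Outside the fences, total cover drops (herbivory halves palatable-species
cover) and Shannon diversity dips while richness is unchanged — deer eat
cover, not species, in this generator. `03_sem_case_study.py` fits the
latent-variable model per treatment and prints Table-style parameter
estimates with standard errors, critical ratios (C.R. = estimate/SE),
standardized coefficients, R² for total cover, and RMSEA — together with
explicit flags when a 12-observation fit turns inadmissible:

```
chi2=12.59 df=13 RMSEA=0.000 PCLOSE=0.5069 R2(Total_Cover)=0.667
inadmissible-solution flags: negative variance: Shannon<->Shannon; ...
```

`04_classical_baselines.py` runs the per-metric ANOVAs (df = 1, 22), the
MANOVA with all four statistics (Wilks Λ, Pillai, Hotelling–Lawley, Roy)
and the canonical contribution ranking, and the backward stepwise
regressions. `05_engine_validation.py` shows the estimation engine is sound
where data suffice — at n = 5000 every parameter is recovered within 3 SE
in ≥96% of replicates — while at the study's n = 12 most fits carry Heywood
flags, and the 10-observations-per-parameter rule of thumb puts the model's
23 free parameters at ~230 required replicates per treatment.

A `multidiv` console command exposes the same pipeline
(`multidiv simulate | metrics | fit | run`).

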