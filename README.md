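# landgen

Landscape genetics of co-dominant microsatellite data: which of plain
geographic distance (IBD), landscape resistance (IBR) or environmental
dissimilarity (IBE) best explains the genetic structure of a set of
populations, and how does local climate shape their diversity?

`landgen` is written for population and conservation geneticists working
with classical multi-population microsatellite surveys — the motivating
system is an alpine cushion plant sampled in three clusters of three
populations across three mountain ranges, but every component is generic.
It bundles, behind one API and CLI:

- **Diversity and Hardy–Weinberg** — allele counts, private alleles,
  observed and unbiased expected heterozygosity (Nei's small-sample
  correction), the multi-locus inbreeding measure *F*is = 1 − *H*o/*H*e, and
  a Monte-Carlo Hardy–Weinberg test (allele shuffling, one-sided toward
  heterozygote deficit).
- **F-statistics** — Weir & Cockerham's θ (the variance-component *F*st
  estimator), pairwise and global; hierarchical *F*-statistics for nested
  designs (individual ⊂ population ⊂ group ⊂ total) from an unbalanced
  nested ANOVA of allele indicators, with bootstrap-over-loci confidence
  intervals; an EM estimator of null-allele frequency and the "excluding
  null alleles" (ENA) correction of θ.
- **Predictor distances** — great-circle geographic distances (optionally
  log-transformed), per-variable climate distances |Δ*T*|, and least-cost
  distances over an elevation raster with an impassability threshold
  (eight-direction moves, Dijkstra), plus the Rousset linearization
  *F*st/(1 − *F*st).
- **Reciprocal causal modeling (RCM)** — pairs of reciprocal partial Mantel
  tests; the relative support of focal hypothesis *H*ᵢ over alternative
  *H*ⱼ is *r*(*G*, *H*ᵢ | *H*ⱼ) − *r*(*G*, *H*ⱼ | *H*ᵢ), and a hypothesis
  whose support column is all positive (row all negative) is *fully
  supported*.
- **Spatial mixed models** — diversity ~ temperature with a Gaussian
  spatial random effect (exponential correlation, profiled range),
  likelihood-ratio tests with Bonferroni correction, marginal AIC ranking,
  and Moran's I residual diagnostics.
- **A forward-time simulator** — Wright–Fisher demes on a synthetic
  three-massif landscape with stepwise-mutating microsatellites and
  migration planted under a known IBD / IBR / IBE / null regime, so every
  stage of the pipeline can be tested against known truth.

## Worked example

Simulate a distance-driven scenario, estimate null-allele-corrected θ, and
ask which hypothesis the data support:

```python
from landgen import (ScenarioConfig, scenario_bundle, read_genepop,
                     read_site_table, read_esri_ascii, pairwise_fst,
                     linearize_fst, geographic_matrix, environment_matrix,
                     least_cost_matrix, ReciprocalCausalModel)

paths = scenario_bundle(ScenarioConfig(scenario="ibd", seed=42), "demo")
sites = read_site_table(paths["sites"])
gt = read_genepop(paths["genotypes"], pop_names=sites.populations)
G = linearize_fst(pairwise_fst(gt, correction="ena").distance_matrix())
raster = read_esri_ascii(paths["raster"])
hyp = {"IBD": geographic_matrix(sites),
       "IBR": least_cost_matrix(raster, sites),
       "IBE-tmin": environment_matrix(sites, "tmin"),
       "IBE-tmax": environment_matrix(sites, "tmax")}
print(ReciprocalCausalModel(G, hyp).fit(n_perm=9999, seed=1).summary())
```

prints

```
(A) relative support (row vs column; winner = positive column)
            IBD    IBR  IBE-tmin  IBE-tmax
IBD       0.000 -0.605    -0.986    -0.953
IBR       0.605  0.000    -0.870    -0.853
IBE-tmin  0.986  0.870     0.000     0.120
IBE-tmax  0.953  0.853    -0.120     0.000

(B) Mantel / partial Mantel correlations (** p<0.002, * p<0.01)
             IBD    IBR IBE-tmin IBE-tmax
IBD       0.76**  0.50*   0.77**   0.77**
IBR        -0.11  0.67*    0.67*    0.68*
IBE-tmin   -0.22  -0.20    -0.19    -0.16
IBE-tmax   -0.18  -0.17    -0.04    -0.11

verdicts:
  IBD: fully_supported
  ...
```

The planted driver (geographic distance) has an all-positive support column
and an all-negative row — fully supported — and its simple and partial
Mantel correlations with genetic distance (panel B, first column) are the
only consistently significant ones.

The packaged nine-population site and diversity tables (Sistema Central,
central Spain) feed the spatial model directly:

```python
from landgen import load_packaged_sites, load_packaged_diversity, SpatialLM

sites = load_packaged_sites()
div = load_packaged_diversity()
print(SpatialLM(div["Ho"], sites, covariate="tmin").fit().summary())
```

```
Spatial linear model (ML)
========================================
response n = 9, covariate = tmin
coef          estimate  [95% CI]
Intercept     1.0699  [ 0.65889,  1.4809]
tmin          0.071234  [ 0.0089884,  0.13348]
lambda (spatial var) = 0.0019098, range rho = 1.666 km
sigma2 resid = 0.0039761
logLik = 10.3748, mAIC = -10.750 (k = 5)
```

Observed heterozygosity rises with annual minimum temperature (positive
slope whose 95% interval excludes zero): the warmer, lower-elevation
populations are the more heterozygous ones in this system.

The same analyses are available from a shell via the `landgen` command
(`simulate`, `diversity`, `fst`, `distances`, `rcm`, `glmm`, and `all`
driven by a YAML config).

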