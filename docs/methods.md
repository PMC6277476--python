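# Methods

This note records the statistical models, estimator conventions, numerical
choices and known limitations behind `landgen`, in the order the pipeline
runs them.

## Data model

Genotypes are unordered diploid allele pairs (positive integer codes) per
individual × locus; a call is either complete or missing — never
half-called. Genepop files encode missing as allele 0; internally a
distinguished sentinel is used and allele 0 never exists. Populations are
named by the Genepop convention (id of the last individual per POP block),
overridable by an explicit sidecar list; the pipeline reconciles Genepop
block order with the site table when names disagree. Missing data are
handled by per-locus (pairwise) deletion throughout; nothing is imputed.

## Diversity estimators

Per population: `n` individuals; `Na` the number of distinct alleles summed
over loci; `PA` private alleles (an allele seen in two or more populations
is private to none); `A` mean alleles per locus; `Ho` the fraction of
non-missing calls that are heterozygous, averaged over loci; `He` the
unbiased expected heterozygosity `2n/(2n−1) · (1 − Σp²)` per locus (Nei's
small-sample correction, with `n` the diploids scored at that locus),
averaged over loci. The inbreeding measure is `Fis = 1 − Ho/He` applied to
the multi-locus means. That is deliberately *not* the Weir–Cockerham
within-population *f*; the two differ, and the simple ratio definition is
used because it is the convention for this kind of per-population summary
table. `He = 0` at every locus leaves `Fis` undefined (NaN with a warning).

## Hardy–Weinberg Monte-Carlo test

The statistic is the observed heterozygote count, compared with its
distribution under random re-pairing of the pooled allele copies within each
locus × population (2000 shuffles by default), one-sided toward deficit —
the direction in which null alleles, inbreeding and substructure push real
microsatellite data. Reported p-values use the add-one rule
`p = (k+1)/(n_iter+1)`, so they are never zero and are conservative at the
resolution of the shuffle count. Monomorphic data return `p = 1` by
convention. For a population-level test the het counts are summed over loci
with independent shuffles per locus. Empirical size at nominal 5% is
0.03–0.05 under simulated exact-HWE nulls (slightly conservative, as the
discrete add-one rule implies).

## Null alleles: EM estimate and the ENA-corrected θ

The null-allele model: one non-amplifying allele at frequency `r` segregates
with the visible alleles under Hardy–Weinberg; null homozygotes appear as
missing calls and visible/null heterozygotes as apparent homozygotes.
The EM iteration treats the latent null-carrier count among observed
homozygotes as missing data (`E[carriers | hom i] = n_ii · 2r/(q_i + 2r)`)
and re-estimates all frequencies from completed counts, to a parameter
tolerance of 1e-8. Because EM contracts geometrically slowly at the `r = 0`
boundary, an estimate that drifts below 1e-2 with no missing data is snapped
to the boundary when the boundary likelihood is at least as good. A locus
with every call missing returns the degenerate `r = 1` with a warning.

Pairwise and global θ follow Weir & Cockerham (1984): per locus and allele
the among-population (a), among-individual (b) and within-individual (c)
variance components, combined across alleles and loci as `θ = Σa / Σ(a+b+c)`.
The "excluding null alleles" correction re-runs the EM per locus ×
population, rescales the visible allele frequencies by `1/(1 − r̂)` and
deflates the effective sample size by `(1 − r̂)` before computing the
components (`ena_deflate_n=False` switches the deflation off; the exact
algebra of the original ENA implementation is not published, so the scheme
is pinned down by two properties instead: it is an exact no-op when
`r̂ = 0`, and it recovers the null-free θ on simulations with planted
masking). Observed heterozygote proportions are left uncorrected — they are
measured on the visible calls and return to the raw value when `r̂ = 0`.

## Hierarchical F-statistics

Variance components for the nesting total ⊃ group ⊃ population ⊃ individual
⊃ gene copy are estimated per locus by Henderson's method I for unbalanced
fully-nested designs, applied to allele indicator variables and pooled over
alleles; the moment equations are solved exactly (the coefficient matrix is
triangular). For a single grouping level this reproduces Weir–Cockerham's
global θ to machine precision — the two code paths are algebraically the
same estimator and are cross-checked against each other and against the
balanced-design textbook recursion in the tests. `F` for fine level ℓ
against coarse level m sums the components strictly between m and ℓ over
the components from m down to the residual, which yields the usual
`F_Pop/T`, `F_Grp/T`, `F_Pop/Grp`, `F_Ind/Pop` grid.

Confidence intervals bootstrap loci (resampling loci with replacement,
B = 1000, percentile 95% intervals): the locus is the only exchangeable unit
that preserves the estimator's structure. Percentile intervals may exclude
the point estimate in pathological resamples; only `low ≤ high` is
guaranteed. A group containing a single population is flagged
low-information rather than rejected.

## Distance matrices

*Geographic*: great-circle (haversine) kilometres on a sphere of radius
6371.0088 km. At sub-continental extents the haversine and planar Euclidean
distances are rank-identical and nearly proportional, and the optional
natural-log transform (the standard linearization against
`Fst/(1−Fst)` for two-dimensional habitats) erases the residual difference
for correlation-based inference. Coincident sites are an error when the log
transform is requested.

*Environmental*: per-variable absolute difference |ΔT| in °C, one matrix per
variable (two separate IBE hypotheses for annual minimum and maximum
temperature rather than one combined climate distance).

*Least-cost*: cells of the elevation raster below the threshold (default
1280 m a.s.l.) or NODATA are impassable; all passable cells have friction 1;
moves go to the eight neighbours and cost the metric step length (the mean
of the two cells' friction times the step, which reduces to pure path length
at uniform friction — the only regime used here). Shortest paths are
Dijkstra on the sparse cell graph. Geographic (degree) rasters use a
per-row cosine correction for east–west step lengths, adequate below ~1°
of extent; projected rasters take site coordinates from `x`/`y` columns.
Sites snap to the centre of their containing cell; disconnected pairs come
back infinite with a warning; output is in metres (Mantel statistics are
scale-invariant, so the unit choice is cosmetic).

*Genetic*: `Fst/(1−Fst)` elementwise, with negative θ estimates floored at
zero (flagged) and entries of 1 rejected.

## Mantel, partial Mantel and reciprocal causal modeling

The Mantel statistic is the Pearson correlation of the n(n−1)/2
upper-triangle entries; its permutation null relabels rows and columns of
one matrix simultaneously, 9999 permutations by default, one-sided
(greater) — the IBD/IBR/IBE hypotheses are directional — with the add-one
correction, so the smallest attainable p is 1/(n_perm+1). The partial
statistic is the Smouse–Long–Sokal residual correlation: genetic and focal
vectors are each OLS-residualized on the control vector and the residuals
correlated; the permutation relabels the *response* (genetic) matrix and
re-residualizes each permuted copy. Controlling for a perfectly collinear
matrix (including A = B) is an error.

RCM runs all ordered pairs of hypotheses. The support table follows the
winner-positive-column orientation: entry (row i, column j) is
`r(G, H_j | H_i) − r(G, H_i | H_j)`, so it is antisymmetric with a zero
diagonal by construction; the diagonal of the correlation panel carries the
simple Mantel r of each hypothesis. Verdicts use the sign rule: fully
supported iff the hypothesis's column is all positive and its row all
negative (zeros break full support), rejected for the mirror image, partial
otherwise.

One caveat the sign rule inherits by construction: because the support
matrix is antisymmetric, "column all positive and row all negative" is
equivalent to "beats every alternative in both reciprocal directions", and
a tournament among k real-valued margins almost always has such a winner —
even when the genetic matrix is pure noise. Under the simulator's null
scenario some hypothesis ends up fully supported in essentially every run,
with the winner roughly uniform among the four (each crowned in ~15–37% of
runs). The sign rule therefore identifies the *best-supported* hypothesis;
it is not a significance filter. The permutation p-values of panel B are
the significance layer: under the null they are calibrated (5% level held
within [0.03, 0.07]), and a sensible reading requires the winning
hypothesis's correlations to be significant before interpreting the verdict.

## Spatial linear mixed model

`y = Xβ + u + ε` over sites, with `u` zero-mean Gaussian with covariance
`σ²_s · exp(−d/ρ)` over great-circle distance and `ε` iid `σ²_e`. The
covariance is parameterized as `σ²_e (I + γ R(ρ))`, `γ = σ²_s/σ²_e`; β and
`σ²_e` have closed-form profiles and `(log γ, log ρ)` are maximized by
Nelder–Mead from a deterministic 2×2 start grid (tolerance 1e-10 on the
log-likelihood); a boundary comparison collapses to the iid fit when the
spatial variance does not improve the likelihood. `correlation="iid"` fixes
the random effect at zero and is exactly ML ordinary least squares — the
natural degenerate case for unreplicated site coordinates. Quadratic terms
center the covariate before squaring to curb collinearity. Reported:
β with Wald 95% intervals from the GLS curvature, `λ = σ²_s`, the fitted
range, the ML log-likelihood and marginal AIC `−2ℓ + 2k` with k counting
fixed effects plus variance parameters. Likelihood-ratio tests compare
nested fits on χ² with df equal to the parameter-count difference,
Bonferroni-multiplied by the number of models screened. Moran's I on
residuals uses inverse-distance weights, the exact expectation −1/(n−1) and
the normality variance.

Exact numerical equality with mixed-model outputs of other packages is not
claimed for the per-study coefficient values: the random-effect structure
behind a printed "(1 | longitude + latitude)" term is ambiguous (site-iid
intercepts vs a smooth spatial field), and fitted coefficients depend on it.
The reproduction surface is the sign and significance pattern, which is
stable across the structures; on the packaged printed tables the minimum-
temperature slope for Ho and He is positive and the centered quadratic term
for allelic richness negative, matching the qualitative conclusions.

## Synthetic landscapes and genotypes

The generator emulates a three-massif alpine system: Gaussian massifs
(peak ~2400 m on a 900 m plain) strung west–east, three demes per massif at
~1850/~2000/~2350 m, temperatures linear in elevation with the residual
scatter of the packaged site table (tmin tightly coupled, tmax noisy), and a
1280 m impassability threshold. The cost surface is made genuinely distinct
from straight-line geography by two devices: a radial barrier wall across
each massif whose only crossing is a gap on the outer flank (so the two
flank demes of a massif are ~14 km apart in a straight line but several-fold
that by least cost), and an asymmetric between-massif topology (the two edge
massifs joined by a direct high route, the central massif reachable only
through a southern corridor — least cost penalizes the geographically
central populations, the opposite of plain distance).

Migration is planted as `m_ij ∝ exp(−d_ij/scale)` with d geographic km
(scale 15 km), least-cost km (scale 30 km) or |Δtmin| (scale 0.3 °C), rows
rescaled to a total emigration of 0.15 per deme per generation (null:
uniform). Genotypes then evolve by Wright–Fisher resampling: each offspring
draws a source deme from its deme's migration row, two parents uniformly
from that deme, one allele per parent per locus (free recombination), then
stepwise mutation ±1 repeat at 3e-4 per copy per generation with reflecting
bounds at repeat sizes 5 and 60 (two-digit Genepop-encodable). The
ancestral state is a diverse refugial pool (uniform ±3 repeats around a
per-locus mode), matching the high heterozygosity of long-established
outcrossing perennials; simulated per-deme He (~0.55–0.70) and alleles per
locus (~4–5 at 20 diploids) land in the empirically typical range. Defaults
are 9 demes, Ne = 100, 8 loci, 500 generations, 20 diploids sampled per
deme. Optional null-allele masking hides each sampled allele copy
independently; under Hardy–Weinberg that is distributionally identical to a
null allele segregating at the masking rate (one hidden copy → apparent
homozygote, two → missing), so the EM estimator's target is exactly the
masking rate.

The kernel scales, total migration and mutation rate were calibrated — that
is the generator's job — so that each planted driver leaves an identifiable
signature at this design size: with 8 loci and 9 demes the across-replicate
(coalescent) variance of pairwise θ is the binding noise floor, and the
walls/corridor geometry concentrates the IBD-vs-IBR contrast on precise
low-θ pairs rather than on a single noisy ridge-level degree of freedom.
Measured over 100 seeds per scenario, the generating driver is
top-supported (largest column-minimum support) in 95–97% of IBD/IBE runs
and 93% of IBR runs. In these known-truth comparisons the IBD hypothesis
matrix is the *untransformed* great-circle distance: the planted kernel is
exponential in raw kilometres, so linearized θ is close to linear in raw
distance, whereas the log transform (the right linearization for
two-dimensional continuous habitats, and the pipeline default for empirical
data) compresses exactly the range where the simulated response varies and
hands the residual to the collinear cost matrix.

What the simulator does not emulate: selection and local adaptation, linked
loci, demographic change through time (expansions, contractions, glacial
cycles), uneven deme sizes, and real DEM texture. Passing recovery tests
therefore show that the inference chain identifies the migration-kernel
driver under neutral equilibrium-ish conditions at the study's sample
sizes — not that it would resolve drivers confounded with history or
selection in real data.

## Problem sizes used by the tests and the acceptance runs

Oracle comparisons use ≤6-population genotype fixtures and ≤5×5 rasters
(exhaustive path enumeration). Calibration studies use 1000 replicates per
test with 199 permutations/shuffles each (p-resolution 0.005 at a 0.05
level). Recovery studies use 100 seeds per scenario at the full default
design, and 20 replicates for the island-model closed-form check
(`θ ≈ 1/(1+4N m)` at `Nm = 1`, ±40% — the closed form itself is an
infinite-island approximation). These sizes were chosen so the whole suite
runs in a couple of minutes while keeping every band comfortably wider than
the Monte-Carlo error of the quantity it brackets.

## Known limitations

- The ENA algebra is a reconstruction constrained by its limit properties,
  not a line-by-line port of the original implementation.
- The HWE test is Monte-Carlo only; no exact enumeration for small samples.
- Least-cost supports isotropic unit friction only (no slope- or
  direction-dependent cost), one raster CRS, no sub-cell interpolation.
- The spatial model is Gaussian-response ML only (no REML, no GLM
  families); bounded summaries like Ho are treated as Gaussian, as is
  conventional for these per-population regressions.
- Mantel-family inference inherits the known sensitivity of partial Mantel
  tests to spatial autocorrelation structure; the RCM sign rule needs the
  significance layer read alongside it (see above).
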