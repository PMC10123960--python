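# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Univariate spike-and-slab regression (BayesC)

Plot-level phenotypes are modeled as

y = Xb + Wα + ε,

where X encodes the intercept, replication, and block nested within
replication (reference-level dummy coding, flat priors; the nested coding
is structurally full-rank, and user-supplied design matrices are rank
checked), W holds raw 0/1/2 dosages, and each marker effect is zero with
probability π or Gaussian N(0, σ²_α) otherwise. π is fixed (default 0.99),
never estimated. Both variances take scaled inverse-χ² priors with ν = 4
degrees of freedom.

**Prior scales.** The residual scale is set so the prior mean of σ²_ε is
`variance_partition` (default ½) of Var(y). For σ²_α the same phenotypic
share is divided by the expected genetic variance carried by the included
markers, (1 − π)·Σ_j 2p_j(1 − p_j), where p_j is the allele frequency.
This mapping from "half the phenotypic variance" to a per-marker scale is
the standard partition used by whole-genome regression software; it is a
documented assumption, and results are insensitive to it whenever the data
dominate (the likelihood concentrates σ²_α quickly once markers enter).

**Gibbs sweep.** Per iteration: (1) fixed effects jointly from their
Gaussian full conditional; (2) for each marker in map order, the inclusion
indicator from its full conditional with the effect integrated out, then
the effect given inclusion, with the residual vector updated incrementally
(numba kernel; uniforms/normals pre-drawn from one seeded Generator so the
chain is bit-reproducible); (3) σ²_α from its scaled inverse-χ² full
conditional over included markers; (4) σ²_ε likewise over residuals.
Zero-variance markers are never included. With m = 0 markers the sampler
reduces to the conjugate Gaussian location model, which is verified against
the analytic posterior by a KS test.

**Summaries.** Per retained (post-burn-in, thinned) draw, the genomic
variance is the empirical variance of Wα across plots — robust to LD,
rather than the theoretical Σ 2p(1−p)σ²_α sum — and heritability is
σ²_g / (σ²_g + σ²_ε / nr) with nr the replication count (default 2),
because genetic signal acts on line means over nr plots. The headline h² is
the posterior mean of the per-draw ratio; the ratio of posterior-mean
variances is also reported (`h2_from_mean_variances_`), as either
convention is defensible. PIP is the fraction of retained draws with a
nonzero effect.

## Bivariate model

The two-trait extension reparameterizes the marker effect as α_j = D_j β_j
with per-trait inclusion indicators δ_j = (δ_j1, δ_j2); all four categories
(0,0), (0,1), (1,0), (1,1) carry prior mass, by default the product of
independent per-trait inclusion probabilities (so (0,0) has 0.9801 under
π_t = 0.99). Categories are sampled with β integrated out under the active
sub-block of Σ_α; for a marker with one active trait the inactive β
component is completed from its conditional prior so the inverse-Wishart
update for Σ_α uses proper 2×2 outer products over markers with at least
one active trait. Σ_ε is updated from the residual cross-product. Both
covariances take inverse-Wishart priors with ν = 4 and scale matrices whose
implied means equal the configured partition of the diagonal phenotypic
(co)variance (zero prior covariance). Non-positive-definite scale matrices
are jittered and retried with a logged count.

The genomic correlation is summarized per retained draw as the Pearson
correlation of the genetic-value vectors Wα₁, Wα₂ (degenerate draws
skipped and counted), consistent with the empirical-σ²_g convention; the
Σ_α-based correlation is reported alongside, and the two agree closely in
simulations. Each manual-trait × spectral-phenotype pair is fit as its own
bivariate model via `fit_pairs`.

## Chain settings and diagnostics

Defaults are 60,000 iterations, 6,000 burn-in, thinning 60 (retaining 900
draws); the test suite and pipeline default to 6,000/600/6, which the
recovery experiments show is sufficient at their problem sizes because the
conjugate sweeps mix quickly. Convergence support: per-parameter trace
plots, effective sample size (Geyer initial monotone sequence estimator,
validated against i.i.d. and AR(1) closed forms), and a Geweke z
(first 10% vs last 50% with ESS-adjusted standard errors); |z| > 2 and
degenerate (constant) chains are flagged.

## Synthetic trial generator

The generator reproduces the statistical skeleton of a two-management
greenhouse trial on a maize diversity panel; its defaults are the real
study's dimensions: 360 lines, 13,826 SNPs on 10 chromosomes, MAF in
[0.05, 0.5], two replications with 6 blocks each, π = 0.99, trait
heritabilities (0.61, 0.60, 0.30), 150 bands over 386–1021 nm, and
band-trait genetic correlations sweeping ±0.39 across the spectrum.

- **LD** is block copy-with-mutation: consecutive blocks of
  `ld_block_size` markers share a base frequency, and each haplotype allele
  copies its neighbour with probability 1 − `ld_flip_rate` (default 0.9).
  This yields controllable positive within-block r² with exact marginal
  frequencies — enough to exercise LD pruning, with no pretense of a
  realistic maize LD map or coalescent ancestry.
- **Effects** are spike-and-slab with jointly Gaussian slab draws across
  traits (correlation `rg_target`); genetic values are rescaled per trait
  so the realized plot-level h² equals the target exactly (residual
  variance 1). Under B+ a fraction of causal loci (default ½) is swapped
  for previously neutral loci with fresh effects, so the two managements
  share genotypes but differ in architecture, mirroring the near-disjoint
  hit sets observed between managements. The distribution of inoculation
  response across lines is not asserted; `management_shift` (default 0.5
  residual SD) and the resampling fraction are free parameters.
- **Design effects** (replication, block) are drawn once per simulation
  from N(0, 0.3²) and treated as fixed unknowns by the samplers.
- **Spectra** are baseline vegetation curves plus a genetic signal mixing
  (i) the manual traits' genetic values through smooth sign-changing
  loadings (peak |correlation| `band_trait_rmax` = 0.39) and (ii) latent
  spectral genetic factors built from the same genotypes, scaled for a
  band heritability near 0.45; plot noise is a smooth random curve plus
  white noise, and reflectance is clipped to [0, 1]. Amplitude is 0.02
  reflectance units per genetic SD — spectra look leaf-like but encode no
  pixel-level morphology.
- **Randomness**: one seed; stages draw from child streams ((seed, 0)
  genotypes, (seed, 1) traits/design, (seed, 2) spectra), so outputs are
  bit-identical given a config.

What passing tests therefore show: the samplers recover heritability,
genetic correlation, and sparse architectures from data whose generative
process matches the model family. They do not show robustness to model
misspecification (non-Gaussian effects, G×E beyond the management split,
population structure, spatial trends), which real trials contain.

## Detection power and the causal-recovery check

With ~10 Gaussian-distributed causal effects carrying h² = 0.5, roughly one
causal marker in ten receives an effect too small to distinguish from null
at n = 1,500 plots — its PIP stays at the null background level regardless
of sampler quality, and finite chains round both weak-causal and null PIPs
toward 0. A requirement that *every* causal PIP exceed a high null quantile
is therefore not attainable under Gaussian effect draws; the recovery test
records this outcome, while heritability recovery itself is comfortably
within ±0.05 at that scale.

## Spectral processing

Index formulas are data-driven `IndexDefinition` records (name, formula
over R(λ)/D(λ), required wavelengths, literature source) with a YAML
round-trip, because published index variants abound and provenance must
travel with the number. Nominal wavelengths resolve to the nearest camera
band (ties to the lower band; targets beyond one grid spacing outside the
range are errors). Derivative terms use central finite differences on the
camera grid; the SD index is the red-edge integral of the first derivative
over 680–780 nm (the sum-of-derivative family). NDNI's SWIR bands
(1510/1680 nm) cannot resolve on a 386–1021 nm camera: the registry keeps
the definition, and evaluation yields NaN with a warning (or an error on
request) — the pipeline analyzes only resolvable indices. Division by zero
or logs of non-positive reflectance yield NaN per plot with a logged
count. Background masking thresholds a reference band (both threshold and
band are exposed parameters; the camera's native cube format is out of
scope — cubes enter as row × col × band arrays).

## Quality control

Markers are removed for call rate < 0.90, then MAF < 0.05 computed on
observed calls of the survivors (both strict inequalities; the ordering
means a marker can only be counted under one rule). Missing dosages are
mean-imputed — a deliberate, documented stand-in for haplotype-based
imputation, adequate at < 10% missingness. LD pruning is exact greedy
left-to-right within chromosome with the earlier-position marker winning,
applied without a window (affordable at panel scale and unambiguous);
whether pruning should be windowed or genome-wide is unspecified upstream,
and within-chromosome greedy is this package's documented choice.
Zero-variance markers have undefined r² and are flagged, never pruned.

## Association and reporting

Threshold comparison is ≥ (inclusive). Gene windows are closed intervals
[pos − flank, pos + flank] clipped at 1; genes match by any intersection on
the same chromosome (containment-based rules would only shrink counts).
PheWAS profiles count (phenotype, management) cells at or above the class
threshold and flag markers shared between manual and hyperspectral
classes. The interactive multiphenotype browser is replaced by
self-contained HTML/SVG with native hover tooltips — no server, one
language. Figures suppress timestamps so reruns are byte-stable, and every
pipeline artifact is content-hashed in a manifest.

## Limitations

- Mean imputation ignores LD information; heavily missing panels should be
  imputed upstream.
- The bivariate runner fits each trait pair independently; no >2-trait or
  factor-analytic covariance models.
- π and the category prior are fixed, not estimated.
- Synthetic spectra share one baseline template; no radiometric or
  atmosphere effects.
- The default 131-index breadth of dedicated spectral libraries is not
  reproduced; the registry ships 25 documented indices and is extensible
  by data, not code.
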