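# Methods

## Generative model of the synthetic twin cohort

Beta values are generated additively on the natural-logit scale and mapped
back through the inverse logit, which keeps β bounded in (0, 1) and makes
M-value analysis the natural testing scale:

```
logit(β_gita) = μ_g + δ_g·[a = 18m] + G_git + E_gi + λ_i(a)·ε_gita
```

for probe *g*, pair *i*, twin *t*, age *a*.  Components, with defaults:

| component | default | meaning |
|---|---|---|
| μ_g | Beta-distributed baseline by island relation | islands hypomethylated (Beta(2,8)), open sea hypermethylated (Beta(6,3)) |
| σ_genetic | 0.15 | SD of the additive genetic draw G; shared exactly by MZ co-twins, correlated ρ = 0.5 between DZ co-twins |
| σ_shared_env | 0.4 | SD of the pair-level shared environment E |
| σ_nonshared | 0.15 | SD of the per-array non-shared/stochastic draw ε |
| σ_technical | 0.04 | SD of the extra logit noise on injected replicate arrays |
| λ_i(a) | 1 at birth; {1.6, 1.0, 0.6} cycled over pairs at 18 m | pair-specific drift factor scaling only the non-shared component |
| δ_g | solves E[β(18m)] − E[β(birth)] = ±0.25 | planted age effect, gain with probability 0.87 |

Non-shared and stochastic factors are modelled as the dominant source of
within-pair variance (σ_genetic ≤ σ_nonshared within-pair contribution):
in buccal tissue the within-pair discordance band is narrow across
zygosities, and the drift/convergence phenomenon itself is attributed to
non-shared influences — hence λ scales only ε.  With the default λ values
the relative change in within-pair Euclidean distance is roughly +60%/−36%
for MZ drift/converge pairs and +33%/−9 to −14% for DZ pairs, comfortably
(or, for DZ convergence, just) beyond the ±10% classification threshold.

**Noise-aware effect planting.**  Because a Gaussian spread on the logit
scale attenuates differences after the inverse-logit (E[expit(x+δ)] −
E[expit(x)] < expit(μ+δ) − expit(μ)), the planted logit offset δ_g is not
`logit(β₀+Δ) − logit(β₀)` but the solution of
`E_Z[expit(μ_g + δ + σZ)] = E_Z[expit(μ_g + σZ)] + Δ` with σ the total
component SD, found by Gauss–Hermite quadrature and vectorized bisection.
Baselines of affected probes are re-drawn so the target marginal stays
inside (0, 1).  This makes the truth table's `true_delta_beta` the value a
perfect analysis would estimate, which is what recall against a |Δβ| > 0.2
cutoff requires.

**Manifest geometry.**  Probes are laid down in blocks of 3–12 probes
spaced 50–800 bp, separated by 5–50 kb — mimicking the locally clustered
spacing of the 450K array.  The minimum block length of 3 equals the
default smoothing window, so no cluster is shorter than the window; this
is a probe-density choice that keeps isolated single probes from carrying
undiluted statistics into the region-detection tail.  Islands are anchored
on a random subset of blocks; each probe's island relation is then
*derived* from its distance to the nearest island edge (inside = island,
≤ 2 kb = shore, ≤ 4 kb = shelf, > 4 kb = open sea).  Planted regions
default to 8 regions of 6–9 consecutive probes: with a 0.995-quantile
threshold over 20k probes (top 100), the ~60 region probes must stay
below the tail quota for the threshold to fall below the region plateau;
more or longer regions would push the cutoff into the plateau and the
spans would fragment.  Region-category odds for planting combine by
taking the strongest enriching odds (categories overlap heavily — most
simulated enhancer probes are intergenic — so multiplying would let the
enhancer category outrank intergenic) and multiplying depleting odds.

**What the simulator does not emulate:** raw intensities and dye biases
(matrices are the entry point), cell-composition heterogeneity, sex-
chromosome biology (sex probes exist only so the removal filter has work),
allele-level genotypes behind the SNP flags, spatially correlated noise
("co-methylation") outside the planted regions, and batch effects.
Passing tests therefore demonstrate the statistical machinery recovers
the planted structure under idealized array noise, not that it would be
robust to every artefact of real 450K data.

## Preprocessing

Stage order: probe detection filter → sample detection filter →
sex-chromosome removal → within-array design-bias adjustment (β) →
β→M transform → between-array quantile normalization (M).

* Probe filter: removed if detection p > 0.001 in one or more samples
  (strictly greater at the boundary).  Sample filter: removed if the mean
  detection p over probes exceeds 0.05.  Both are idempotent.
* M = log₂(β/(1−β)) with β clipped to [10⁻⁶, 1−10⁻⁶]; intensities are out
  of scope, and β/M are equivalent up to this clipping.
* Design-bias adjustment: per array and island-relation stratum, type II
  β values are mapped onto the empirical quantiles of a random subset
  (≤ 5000) of the stratum's type I probes via mid-rank plotting positions
  — a simplified, deterministic within-array normalization of the
  Infinium I/II difference.  The map is monotone, so type II rank order is
  preserved within each stratum.  Strata with fewer than 10 type I probes
  are left unchanged with a warning.
* Quantile normalization: every column is forced onto the row-mean
  reference distribution; tied input values receive the mean of the
  reference values over their tied ranks.  On tie-free input this matches
  limma's `normalizeQuantiles` (checked against Rscript in the tests).

## Differential testing

The paired birth/18-month design is tested as a one-sample problem on
within-individual M differences (replicate arrays averaged first;
individuals missing a timepoint dropped).  The prior (d₀, s₀²) is the
moment estimator on log variances: solve trigamma(d₀/2) = Var(e) −
trigamma(df/2) by monotone Brent root-finding, with d₀ = ∞ (common
variance) when the observed spread does not exceed the sampling noise.
Probes with n < 3 are excluded from prior estimation but still tested.
Effect direction (gain/loss) follows the sign of the mean paired β
difference computed on normalized β, matching the |Δβ| > 0.2 stringent
cutoff scale.  d₀ = 0 reproduces the classic paired t-test exactly and is
the fallback when no positive variances exist (identical arrays).

The biological-vs-technical contrast is run per replicate pair: co-twin
differences within each (age, replicate) versus replicate differences
within each (twin, age), each through the same moderated pipeline, with
per-pair and union significant counts.  A pooled across-pair co-twin test
would have expectation zero and could not express the contrast.

## Region detection

Greedy gap chaining (≤ 1 kb) defines clusters; a centered running mean
(window 3, edge-truncated, clusters shorter than the window unchanged)
smooths the t̃ statistics; the threshold is the 0.995 quantile of
|smoothed t̃| over all probes — read as a quantile because a literal
t = 0.995 cutoff would be meaninglessly permissive; maximal same-sign
runs of ≥ 4 consecutive probes above threshold become regions, ranked by
area.  A running mean replaces loess: deterministic, parameter-light and
adequate at array probe density.  Reported coordinates are 0-based
half-open spanning first to last probe plus one site width.

## Enrichment

Observed/expected against the QC-passing autosomal universe (not the full
manifest), with hypergeometric upper tails for enrichment and lower tails
reported when the ratio is < 1 (depletion).  Raw significance tiers
(0.05 / 10⁻²⁰ / 10⁻⁵⁰) are flagged without cross-category correction;
the output notes the tail used per row.

## Discordance and dynamics

Probe-wise discordance and Euclidean distances are computed on normalized
β (the residual-model variant on M is also exposed, with residuals about
the (pair, timepoint) group mean).  The drift/converge/stable boundary is
a ±10% relative change in Euclidean distance — scale-free, conservative
for the narrow distance band the design produces, and configurable; the
choice of a numeric boundary is this package's own, as is computing
distances over all analysis probes rather than the > 0.2-discordant
subset.  Ranked gene lists deduplicate by best rank, break metric ties by
probe id, and exclude intergenic probes.

## Numerical and degenerate-input choices

* All simulator randomness flows from one `SeedSequence` per cohort with
  deterministically derived substreams (per pair, detection layer,
  replicate injection); regeneration with the same seed is bit-identical.
* Boundary conventions: detection thresholds retain at equality; the
  > 0.2 discordance and |Δβ| cutoffs are strict; the ± 5 kb TSS window is
  closed.
* Zero birth-distance pairs classify as stable with a warning; singleton
  residual groups get residual 0 with a warning; empty SNP subsets warn
  and downstream clustering refuses them.
* Distance ties in mutual-nearest-neighbour pairing break by
  lexicographic sample id; "co-twins cluster together" is mutual nearest
  neighbourship (deterministic and linkage-free; the dendrogram-sibling
  variant is provided).

## Problem sizes

Defaults are a 20k-probe, 15-pair cohort (~1.5 s per full pipeline run).
The test suite and the reproduction script use 10 seeds for recovery
checks, 20 for the null and replicate-contrast checks, and 10k-probe
cohorts for the replicate contrast — sizes at which every Monte-Carlo
margin in the checks is several standard errors wide.
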