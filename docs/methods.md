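# Methods

This package reimplements, as a tested library, the combined
quantitative-genetics and population-genetics workflow used to dissect an
X-linked QTL for chill-coma recovery time (CCRT) in *Drosophila
melanogaster*: deficiency complementation mapping, windowed diversity and
differentiation statistics, a composite-likelihood sweep scan with a
simulation-calibrated threshold, a per-SNP differentiation scan with cline
regression, and qPCR relative-expression analysis.  This note records the
models, the parameter choices that matter, and the design decisions taken
where the workflow leaves them open.

## Coordinates, masking and site classification (`alignment`)

All coordinates are 1-based inclusive; BED exports convert to 0-based
half-open.  Two quality rules are applied before any statistic:

* per-base PHRED masking — calls with PHRED < 21 become N (strictly below;
  a call at exactly 21 is kept);
* site exclusion — a site whose pooled fraction of N calls is **strictly**
  above 10% is excluded.  The rule is applied to the pooled analysis sample,
  not per population; per-population call-rate thresholds belong to the SNP
  scan (where the rule is ≥ 50% calls in *every* population).

Gap characters are treated as missing — conservative, since the sources of
gaps in consensus alignments cannot be distinguished from no-calls.
Multiallelic sites are excluded from every downstream statistic (this keeps
the frequency-spectrum algebra biallelic and matches the SNP-scan exclusion
rule).  The pipeline order is fixed: mask → classify → filter.

## Windowed statistics (`windows`)

Statistics are computed on 2-kb non-overlapping windows by default, with a
flagged partial window at the end of the region.  Missing data are handled
per site: every estimator uses that site's own valid sample size `n_i`.

* θπ: per segregating site, `2·x·(n_i − x) / (n_i·(n_i − 1))`, summed and
  divided by the count of valid (non-excluded) sites L_valid.
* θW: per segregating site `1/a(n_i)` with `a(m) = Σ_{k<m} 1/k`, divided by
  L_valid.
* Dxy: per site, the fraction of sample alleles differing from the outgroup
  base; sites with an outgroup N are dropped from both numerator and
  L_valid.  Sites polymorphic within the sample are included with
  fractional weight.
* Tajima's D uses window totals (Θπ and S) with the standard constants.
  Because missing data leave no single n, the constants use the median
  per-site `n_i` over the window's segregating sites, rounded down (the
  mean is available by option).  D is reported as NaN — not 0 — when S = 0.
* Pairwise FST is the normalized heterozygosity deficit
  `(H_B − H̄_W)/H_B`, with H_B the mean between-population pairwise
  difference and H̄_W the mean of the two within-population diversities,
  aggregated over the window.  Of the several "Nei normalized distance"
  variants this is the Hudson-style form; alternatives differ by
  sample-size correction terms of order 1/n.  Negative values are reported
  as computed with a `clipped` flag rather than silently zeroed.

Windows with fewer than 50% valid sites are reported but flagged
low-confidence.  θπ, θW and Dxy are reported per site (published per-window
magnitudes of ~10⁻³ confirm per-site scaling); D is unitless.

## Frequency spectra and the sweep transform (`sfs`)

Derived-allele classes are polarized against the outgroup; sites whose
outgroup base matches neither allele are dropped and counted as
polarization failures.  Sites with more valid calls than the target sample
size are projected down by hypergeometric sampling
(`q_m(i) = Σ_j p_n(j)·H(i; m, j, n)`); smaller sites are dropped.

An *extended* spectrum carries two invariant classes in addition to the
polymorphic classes 1..n−1: class 0 (monomorphic ancestral) and class n
(monomorphic derived), populated **only** by sites monomorphic in the focal
sample and polymorphic in a reference sample.  These are exactly the sites
a recent sweep converts from polymorphic to invariant, so carrying them
raises the power of the scan.  The two classes are kept split (ancestral
vs derived) rather than pooled — the split carries strictly more
information and costs nothing.

The sweep transform follows the classic star-like approximation: at escape
probability p_e each of the n lineages independently escapes the sweeping
haplotype; the trapped lineages coalesce into one ancestral lineage, so a
draw of B escapees leaves an effective pre-sweep sample of B+1 whose
derived count follows the background spectrum projected to B+1; the
representative lineage's state is inherited by all n−B trapped lineages.
The implementation is validated to 10⁻¹⁵ against an exhaustive
lineage-enumeration oracle for n ≤ 6, and the transform is continuous in
p_e with rows summing to 1.

## Composite likelihood ratio scan (`sweep`)

At grid position g the statistic is
`Λ = clr_scale · (max_α ℓ_sweep(α) − ℓ_neutral)`, floored at 0, with
`p_e = 1 − exp(−α·d)` at distance d and the per-site likelihoods taken from
the sweep-transformed and background spectra.  Conventions:

* `clr_scale` defaults to 2 (a likelihood-ratio scale); published CLR
  profiles from other tools may use a factor-1 convention, so the scale is
  a config constant.
* α is per base pair and maximized over a log-spaced grid (default 64
  points, 10⁻⁸..10⁻² per bp) rather than by continuous optimization —
  reproducible and robust; the grid can be refined.
* Two likelihood modes share one code path.  Data carrying the extended
  invariant classes use the full extended spectra.  Variant-only data
  (e.g. coalescent simulations, which cannot supply reference-conditioned
  invariant sites) use both spectra renormalized over classes 1..n−1,
  i.e. the likelihood conditions on segregation.  A threshold calibrated in
  one mode applies only to scans in the same mode.
* Site classes with zero background probability are excluded from both
  likelihoods with a warning.
* Numerics: the sweep spectrum is tabulated on a uniform 4096-point p_e
  grid and looked up by nearest neighbour (CLR error < 0.1 at statistic
  values of tens); the degenerate p_e = 0 row of the conditional table is
  replaced by the p_e → 0 limit (equal mass on classes 1 and n−1).

### Threshold calibration

Significance is calibrated by simulating batches of neutral datasets of
increasing length, scanning each, and recording the batch maxima; the
threshold is the 95th quantile of maxima at the plateau of the
q95-vs-length curve.  The plateau rule declares a plateau at the first
length whose q95 changes by less than 5% (relative) from the previous one.
At desk scale the curve grows roughly logarithmically in region length —
the maximum over ~L/ℓ independent stretches has Gumbel-type growth — so the
5% rule genuinely triggers only when q95 is already large relative to the
per-doubling increment (multi-megabase scale); when no plateau is reached
the largest-length quantile is returned with a `no_plateau` flag, which is
the expected desk-scale outcome.  If no background spectrum is supplied,
one is estimated by pooling extra neutral replicates, so the neutral model
is calibrated exactly as in a real scan.  The whole curve is reproducible
from one seed.

Default desk-scale calibration: lengths 50–400 kb in doublings, 60
replicates per batch, one grid point per kb, 32-point α grid.  A
full-scale run (5 Mb regions, batches of 100, denser grids) is reachable
through the same configuration parameters.

## Synthetic data (`simulate`)

All generators are pure functions of (config, seed).

* **Coalescent haplotypes** — msprime ancestry (haploid samples,
  recombination, piecewise-constant demography) with infinite-sites binary
  mutations on continuous positions.  Population sizes are haploid counts
  and epoch times generations; `theta` and `rho` are per-site rates
  referred to the most recent epoch size N0 (μ = θ/(2N0)), so a
  constant-size model satisfies E[π] = θ and E[S] = θ·L·a(n) — both checked
  against closed forms in the tests.  Positions are snapped to unique
  integer coordinates by shifting collisions to the next free coordinate;
  dropping collided sites instead would bias diversity estimators downward
  by about θ·S/L (≈2% at θ = 0.01 over 50 kb), which is measurable at the
  test suite's precision.
* **Toy bottleneck demography** — a severe reduction (10⁶ → 4·10⁴ haploid)
  20–60 k generations ago with recovery to the ancestral size.  The
  parameters are illustrative, chosen only to reproduce the qualitative
  Europe-vs-Africa diversity reduction; inference-derived demographies are
  user-suppliable and never hard-coded as truth.
* **Sweep-spectrum site sampler** — positions uniform on the region, each
  site's class drawn from the sweep transform at its own p_e.  This matches
  the scan's model by construction and is used for power and localization
  experiments, not as a genealogical sweep simulation (no trajectory model,
  no linkage between sites).
* **CCRT phenotypes** — a 2×2 design (line E/A × background deletion/
  balancer) on the log-minutes scale with additive and interaction effects
  and Gaussian noise; recovery times are rounded up to whole minutes, the
  scoring resolution.  Defaults: 35 flies per cell (the published average),
  baseline exp(μ) = 32 min, residual SD 0.25 on the log scale (giving
  cell SDs of ~7–9 min at 30-min means, the magnitude seen in the published
  tables).
* **qPCR Cq tables** — Cq = base − log_E(quantity) + pool offset +
  technical noise; quantity = 2^(log2 fold).  The pool offset (SD 0.3
  cycles) models RNA-loading differences shared by all genes of a pool and
  cancels under reference-gene normalization; technical noise defaults to
  0.15 cycles.  Reference genes are constrained flat.  Defaults mirror the
  published design: two populations × three treatments × three pools ×
  triplicates.

What the generators do **not** emulate: sequencing/alignment error,
linked selection in the neutral background, batch effects between qPCR
runs, or non-lognormal phenotype tails.  Passing tests therefore show the
estimators and decision rules are correct and calibrated under the stated
models, not that real data meet those models.

## Complementation mapping (`complementation`, `intervals`, `tables`)

CCRT observations are analysed by fixed-effects two-way ANOVA on
natural-log minutes (the log base cannot change F statistics; natural log
is the documented choice), with Type-II sums of squares for unbalanced
cells (statsmodels `anova_lm`).  Published per-fly data are unavailable, so
printed P-values are not reproduction targets; the printed genotype means
are, via the delta arithmetic:

* Δdef = mean(E/def) − mean(A/def), Δbal = mean(E/bal) − mean(A/bal),
  on the original minutes scale.

Failure to complement requires statistics *and* direction: p_L and p_L×G
below the cut (0.01 for a high-confidence call, the working level α = 0.05
for a marginal one, Bonferroni-adjustable over the batch of m deletions,
default m = 1 with m = 24 the published batch size) **and**
|Δdef| > |Δbal| with Δdef < 0 (the temperate chromosome must recover faster
specifically when the deletion uncovers it).  Direction failures are called
`complement` no matter how small the p-values.

Candidate intervals are refined by subtracting every overlapping deletion
that complements; interval arithmetic is closed-inclusive with lengths
end − start + 1, and kb rounding happens only at display time.  Genes are
assigned to intervals by ≥ 1 bp overlap.

## Differentiation scan and clines (`diffscan`)

SNPs are retained when biallelic with at least 50% of base calls in every
population (strictly-less-than-50% excludes).  Per SNP the global FST is
`(H_T − H̄_S)/H_T`, with H_T from the sample-size-weighted pooled
frequency and H̄_S the unweighted mean within-population expected
heterozygosity; SNPs monomorphic overall are flagged undefined.  Outliers
are the empirical upper quantile of the panel (ties inclusive).  A
reversible-jump Bayesian FST decomposition is deliberately **not**
reimplemented — its locus effects and q-values are tool- and data-bound —
and the empirical-quantile flagging is a labelled replacement, not an
equivalence claim.

Cline regression fits frequency on |latitude| by OLS separately for the
hemispheres north and south of the equator (equatorial populations anchor
both fits), returning slope, intercept and the slope t-test p-value per
hemisphere; a joint signed-latitude fit is available by option.

## qPCR expression analysis (`cnrq`)

Technical replicates are averaged on the Cq scale first (the qBase
convention; averaging after conversion is possible by composing the steps
manually and gives different results).  Then per gene, with amplification
efficiency E from dilution series: RQ = E^(ΔCq against the calibrator
group's mean Cq); NRQ = RQ / geometric mean of the reference-gene RQs in
the same pool; CNRQ = NRQ rescaled so the calibration group (the tropical
control) has geometric mean 1.  Confidence intervals propagate the
technical SD of the mean Cq on the log2 scale through Student t with
n_tech − 1 df and are rescaled identically.

Contrasts are screened before testing: a contrast is tested only when its
|log2 fold| exceeds k times the gene's pooled technical log2 SD (k = 2 by
default; the screen constant and scale are config since only "defined by
the variance between technical replicates" is specified).  Screened-in
contrasts get Welch two-sample t-tests on log CNRQ and Benjamini–Hochberg
correction across all performed tests, with display tiers at
0.05/0.01/0.001.

## Validation strategy (`validation`, `scripts/acceptance.py`)

The study's data-bound numbers (published diversity tables, the
chromosomal CLR threshold value, Bayesian outlier statistics, expression
figures) cannot be recomputed without the original sequence downloads and
unpublished demographic parameters.  Validation is therefore by recovery:

* delta arithmetic and the failure-to-complement decision rule applied to
  the published summary tables (exact);
* the refined 124-kb candidate interval length (exact);
* neutral estimator recovery: 1000 replicates, n = 20, θ = ρ = 0.01/bp,
  50 kb — θπ and θW within ±3 SE of θ, mean Tajima's D within ±0.15 of 0
  (per-replicate π is right-skewed, so the replicate count is kept high
  enough that single extreme genealogies cannot dominate the band);
* the sweep transform against exhaustive enumeration (n ≤ 6, 10⁻¹⁰);
* CLR calibration: neutral 50-kb regions exceed the calibrated threshold
  at no more than the calibration quantile's rate; sweep-sampled data
  localize the simulated center within 10% of the region length in ≥ 80%
  of replicates; the q95 curve rises with length (positive rank
  correlation) and flattens in relative terms;
* ANOVA calibration: the high-confidence fail call fires on null phenotype
  data at ≤ 1% (1000 replicates, Bonferroni m = 24);
* qPCR round trip: known log2 folds recovered within ±0.2 through the full
  Cq → CNRQ pipeline.

Problem sizes in the validation experiments (batch sizes, region lengths,
replicate counts) are desk-scale choices of this package; every experiment
is reproducible from a single seed.

## Known limitations

* The sweep site sampler draws site classes independently; it carries no
  linkage disequilibrium, so power estimates against it are optimistic
  relative to genealogically simulated sweeps.
* The conditional (variant-only) CLR mode cannot use the invariant-class
  signal, the main power booster of the extended mode; thresholds are
  mode-specific.
* FST forms differing by 1/n correction terms will disagree slightly with
  the windowed estimator on small samples.
* The ANOVA treats line and background as fixed effects with a common
  residual variance; heteroscedastic cells are not modelled.
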