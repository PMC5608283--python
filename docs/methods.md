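# Methods

`tripla` detects **three-way gene interactions with a switching mechanism**:
a conditioning gene X3 whose expression level modulates the co-expression of
a gene pair {X1, X2}, so that the pair is directly correlated when X3 is high
and inversely correlated when X3 is low (or vice versa).  Classical pairwise
co-expression analysis averages over the states of X3 and misses such pairs.
The package implements the full analysis chain for a two-group expression
study (e.g. wild-type vs transgenic animals, ~15 + 15 arrays): candidate
selection, a genome-scale liquid-association triplet scan, conditioned
correlation decomposition, gene-set enrichment consistency checks, and a
mutual-information regulatory network in which significant triplets are
traced.

## Preprocessing

**Probe collapsing.** When several probes map to one gene, the probe with the
largest interquartile range is retained (quartiles by linear interpolation;
ties broken by the lexicographically smallest probe id).  Output rows are
always verbatim input rows.

**Normal-quantile transform.** Each gene's values are replaced by
Φ⁻¹(rᵢ/(n+1)), with average ranks on ties.  The i/(n+1) plotting position is
the convention under which a tie-free 30-sample profile has tertile
boundaries ±Φ⁻¹(20/31) = ±0.372 and extremes ±Φ⁻¹(30/31) = ±1.849 — the
values conditioned-correlation figures print as ±0.37 and ±1.84 (the upper
extreme is truncation- rather than rounding-consistent, 1.8486 → 1.84).
Conditioned-correlation boundaries are therefore reported on this quantile
scale; the liquid-association statistics use the additionally standardized
values (zero mean, unit n−1 SD), as the estimator expects.  At finite n the
sample SD of the quantile scores is slightly below 1, so standardization
stretches the scale by ~9% at n = 30; correlations are unaffected.

## Candidate switching genes

A switching gene must differ in mean between the two groups.  Each gene gets
an ordinary two-group linear fit (difference of means, pooled residual
variance s²_g on d = n − 2 df).  The variances are shrunk toward a prior
s₀² with d₀ prior df, estimated by the closed-form method of moments on
log s²_g (matching the empirical-Bayes moderated t of limma's `eBayes`; the
trigamma inversion uses Newton iteration to 1e-8).  The moderated statistic
is t = Δmean / (s̃_g √(1/n₁+1/n₂)) on d₀ + d df, with d₀ = ∞ (all s̃² = s₀²)
when the log-variances are underdispersed and d₀ = 0 (ordinary t) when no
prior can be fitted.  Two-sided p-values are BH-adjusted; candidates are
genes with q below a configurable threshold (default 0.05).  Agreement with
Bioconductor limma is asserted in the test suite (t and p to ~1e-6).

## The binned liquid-association statistic

For transformed vectors and M bins,

    MLA(X1, X2 | X3) = (1/M) Σᵢ ρ̂ᵢ · x̄₃ᵢ ,

where samples are ordered by X3 (stable sort; ties keep input order) and
split into M contiguous equal-count bins (remainder spread one-extra into the
first bins); ρ̂ᵢ is the within-bin Pearson correlation of the pair and x̄₃ᵢ
the within-bin mean of X3.  A bin in which either pair gene is constant
contributes ρ̂ᵢ = 0 rather than aborting a genome-scale scan.  M defaults to
3 for n ≈ 30, consistent with the tertile presentation of conditioned
correlations; it is a flag everywhere.  The mean-triple-product liquid
association (1/n) Σ x1ᵢx2ᵢx3ᵢ is computed alongside as a companion.

Exact invariants: symmetry in (X1, X2); sign change under negation of X1 or
X2; a perfectly correlated unmodulated pair scores exactly mean(X3) = 0 with
equal bins.  The implementation is checked against an independent explicit-
loop oracle to 1e-12.

### Significance

Three constructions are provided:

- **permutation** — X3 is permuted against the pair `n_perm` times and
  p = (1 + #{|MLA*| ≥ |MLA|})/(n_perm + 1).  Exactly calibrated (the add-one
  estimator keeps p > 0), resolution limited to ~1/n_perm.
- **normal_approx** — two-sided normal tail with the null SD taken from a
  pilot permutation set (≥ 200 draws).
- **analytic** — delta-method SE from plug-in per-bin correlation variances,
  SE² = (1/M²) Σᵢ x̄₃ᵢ²(1 − ρ̂ᵢ²)²/(nᵢ − 1), two-sided normal tail.

The scan defaults to the **analytic** p.  The reason is structural: at
n = 30, M = 3 the statistic is bounded (|MLA| ≤ (|x̄₃,low| + |x̄₃,high|)/3 ≈
0.69) and a strongly modulated triplet sits only ~3-4 permutation SDs from
the null, so permutation-based p-values cannot fall below ~1e-4 — far above
the ~1e-5–1e-7 needed to clear BH across tens of thousands of triplets.
Genome-scale LA scans that report such tiny p-values at n = 30 necessarily
rely on an analytic tail.  The delta-method z is approximately standard
normal under the null at moderate levels (checked against permutation in the
tests), but its far tail is **anti-conservative**: when |ρ̂ᵢ| is large by
chance the plug-in variance shrinks and z inflates.  Calibrated inference at
achievable resolutions should use `method="permutation"`/`"normal_approx"`;
the analytic default reproduces the field's scan behaviour and is flagged as
such wherever it appears.

### Scan, retention and FDR

All (candidate X3) × (unordered pair) triplets are enumerated, with pairs
allowed to contain other candidates and the pair stored in sorted-id order.
The `top_k` most significant triplets (default 300 000) are retained and BH
runs **within the retained set** — the convention of the emulated analysis,
anti-conservative relative to correcting over the full enumeration; pass
`correct_full=True` to use the total enumeration count in the correction.
Both the 0.05 and 0.001 FDR presets of the emulated analysis are reachable
through the `fdr` parameter (default 0.05, the convention under which
triplet counts are reported).  Results are ranked by |MLA| then p, and the
scan is deterministic given its seed.

## Conditioned correlations

Samples are split into low/middle/high rank strata of X3 (tertiles by
default; a remainder of 1 goes to the middle stratum, a remainder of 2 to
the two outer strata, keeping the split symmetric).  Pearson correlations
are computed per stratum; a zero-variance stratum yields a missing value,
never 0.  Reported boundaries are the middle stratum's endpoint values on
the quantile scale (±0.37 at n = 30) with the observed extremes (±1.85).

## Enrichment

Right-sided hypergeometric tests with exact big-integer tail sums (no
floating drift; the p for printed counts (N, m, q, k) is reproducible to
1e-12), BH over all tested terms, then filtering at p < 0.05 and FDR < 0.1
by default.  The universe is the intersection of annotation genes and
measured genes — the standard conservative choice; terms emptied by the
intersection are dropped.  Annotation arrives as a GMT file.  Two
consistency analyses mirror the emulated study: the common-term overlap
between the X3 group and the all-triplet-genes group, and a control that
draws 30 random subsets of 35 genes from the larger group and counts how
rarely their enriched terms overlap the reference set.

## Regulatory network

Pairwise dependence is plug-in mutual information (nats) on an
equal-frequency B × B grid, B = ⌊√(n/5)⌋ clipped to [2, 10], with the
Miller–Madow correction (Kx + Ky − Kxy − 1)/(2n) added and the result
clipped at 0.  A constant gene has MI 0 by convention.

The significance threshold is the (1 − α) quantile of the permutation null.
Because the marginals are equal-frequency patterns, the null law depends
only on a uniform random permutation pairing the two label patterns, so the
null is sampled exactly and cheaply by permuting the pattern — no data
resampling.  For α below the permutation resolution an exponential tail is
fitted to the top exceedances (threshold u at the 95th percentile or the
top 100 draws, rate from the mean exceedance).  The default α = 1e-4
matches the emulated analysis.

Edges below threshold are removed; the data-processing inequality then
deletes, in every triangle, the weakest edge when its MI is below
(1 − tolerance) × the second-smallest (tolerance 0.15 by default, common
ARACNE practice; tolerance 1 disables pruning).  Surviving edges incident
to a hub marker (the candidate switching genes) are directed hub → target —
a bookkeeping convention, not causal orientation; hub–hub edges keep both
directions.  Gaussian-kernel MI estimators used by some ARACNE
implementations are intentionally not reproduced; node/edge counts of such
networks are therefore only indicative.  Finally, each significant
triplet's X3 is connected to its X1 and X2 through directed network paths
of length ≤ 2 (one intermediate regulator admitted), verified in tests
against exhaustive path enumeration.

## Synthetic data generator

The generator emulates the target study design: n = 30 samples split
15/15 into two groups, a small set of differentially expressed genes
(group-2 mean shift 1.5 SD by default — a moderate microarray effect), and
planted triplets.  Each planted X3 is standard normal plus the group shift
(so the DE filter can find it, matching the candidate definition); given the
observed X3 value z, the pair is bivariate normal with unit variances and
correlation

    ρ(z) = ρ_max · tanh(γ z),      defaults γ = 5, ρ_max = 0.9,

sampled exactly through the 2 × 2 Cholesky factor per sample.  tanh is the
simplest smooth, bounded, sign-symmetric law realizing the tertile sign
flip.  Background genes are independent Gaussian noise.  A matched null
generator emits fully independent genes for type-I calibration.  Everything
is byte-deterministic given the seed.

What the generator does **not** emulate: probe-level measurement error,
RMA/background correction, batch or array-quality effects, heavy-tailed
intensities, and correlated background co-expression modules.  Passing
recovery tests therefore demonstrate correctness of the estimators and
plumbing under the stated generative law, not performance on real arrays —
where correlated backgrounds will inflate the scan's null.

## Problem sizes and test design

The test suite and acceptance checks run at desk scale, chosen as the
smallest sizes at which each property is identifiable: 115 genes / 5 planted
triplets for scan recovery (32 205 triplets), 2000 null triplets at 499
permutations for calibration, n = 200–400 for network recovery, 100 random
instances for oracle equivalence.  The full-size conventions of the emulated
study (300 000 retained triplets, 20 000+ genes) are reachable through the
same parameters.

## Known limitations

- At n = 30 the binned statistic is bounded (~0.69 at M = 3), so ranking by
  |MLA| cannot cleanly separate strongly modulated triplets from the extreme
  order statistics of tens of thousands of null triplets; recovery relies on
  the analytic p-value, whose far tail is anti-conservative (above).  A
  scan that needs calibrated FDR at these sample sizes should use
  `correct_full=True` with permutation-based p-values and expect materially
  fewer discoveries.
- BH within the retained top-K inherits the emulated analysis's
  anti-conservatism.
- Enrichment conclusions depend on the annotation release supplied as GMT;
  term-count reproductions across annotation versions are out of scope.
- The moderated t assumes a common two-level design without array weights,
  blocking or multi-factor structure.
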