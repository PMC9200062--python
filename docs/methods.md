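# Methods notes

This note records the statistical models behind `lncmeth`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-engineer
from the code.

## Preprocessing contracts

Methylation arrives as probe-level β ∈ [0,1] with **zero as the missing
sentinel** — this reading is implied by the imputation rule "fill with the
mean of the non-zero values", which only makes sense if zero marks absence.
The fixed order is filter → impute → promoter-average: probes must be
positive in *strictly more than* 50% of samples (the thresholds here and in
the 70% expression presence rule are strict because the rules are phrased as
"more than"), imputation replaces each zero with the probe's non-zero mean
(preserving that mean exactly), and a lncRNA's promoter methylation is the
unweighted mean of its surviving probes. The promoter window itself is
delegated to the probe→lncRNA map supplied as input; the package does not
fix a TSS±N definition. Expression missingness, by contrast, is explicit
(NaN): RPKM zero is a real measurement, not a gap. Duplicate gene symbols
after ID harmonisation collapse by mean — an arbitrary but deterministic
choice; anything order-dependent (first wins) would tie results to input
ordering.

## Moderated two-group test

Per feature, the pooled two-group variance s² (d = n₁+n₂−2 df) is shrunk
toward a prior s₀² with d₀ prior df:

    s̃² = (d₀ s₀² + d s²) / (d₀ + d),   t̃ = logFC / (s̃ √(1/n₁ + 1/n₂)),

with p-values from t on d₀+d df. The prior is fitted by closed-form moment
matching on log s²: with e = log s² − ψ(d/2) + log(d/2), solve
ψ′(d₀/2) = var(e) − ψ′(d/2) by Newton inversion of the trigamma function and
set s₀² from the mean of e. Moment matching (rather than MLE) is
deterministic, cheap, and accurate at the feature counts involved; when the
observed log-variances are no more dispersed than sampling alone explains,
d₀ = ∞ and every feature gets the common variance (normal reference
distribution). d₀ = 0 recovers the ordinary pooled t exactly, which is the
oracle equivalence the tests assert. Zero-variance features are excluded
from the prior fit but still receive a shrunken variance; an all-constant
matrix is an error.

**Methylation test scale.** A |log₂ fold-change| > 1 rule cannot be met by
values bounded in [0,1], so the moderated test runs on M-values
log2(β/(1−β)) with a 1e-6 boundary clamp; "logFC" for methylation is
therefore an M-value difference. The raw-β and log2(β) scales remain
selectable for sensitivity analyses. Δβ and the reported group means always
use the raw β scale. FDR control is Benjamini–Hochberg (the conventional
default of the moderated-t ecosystem). Direction calls are a strict
conjunction: Δβ > 0.1 (methylation only), |logFC| > 1, q < 0.05, with the
sign taken from the group-mean difference; they are exactly antisymmetric
under swapping the group labels.

## Set integration

"Cancer-specific" uses the stricter of the two possible readings: a lncRNA
is specific to cancer c only if it is differentially methylated in **no**
other cancer in **either** direction (the per-direction reading is available
via `strict=False`). Cancer-common membership counts either direction and
reports the per-cancer direction profile rather than enforcing concordance,
because common dysregulation with heterogeneous direction is itself
informative. Negatively correlated lncRNAs are the set-level intersection
UMLE = meth-up ∩ expr-down and DMOE = meth-down ∩ expr-up; no per-sample
correlation is computed at this stage — the negative relation is asserted at
the call level, mirroring how the catalogs are built.

## ceRNA screen

The miRNA universe N for the hypergeometric test is the union of all miRNAs
appearing in either target map; the test is upper-tail (shared-target
excess), and "more than two shared miRNAs" is strict (k ≥ 3). Correlations
are computed on tumor samples only — the network is meant to describe tumor
co-expression — with the two-sided p from t = r√((n−2)/(1−r²)) on n−2 df.
Neither p-value is multiplicity-corrected by default, matching the screen's
design as a raw-threshold filter; BH correction of either step is a config
switch. The filters are a pure conjunction, so relaxing any one can only
grow the network.

## Survival cut-points

Each sample receives a log-rank (Nelson–Aalen) score aᵢ = δᵢ − Λ̂(tᵢ); for a
cut placing the m lowest-expression samples in the low group, the
standardized statistic is

    z_m = Σ_high (aᵢ−ā) / √( m(n−m)/(n(n−1)) · Σ(aᵢ−ā)² ),

and the maximally selected statistic is max|z_m| over admissible cuts (both
sides at least ⌈0.1·n⌉ samples, cuts only between distinct expression
values, ties share a side, the reported cut is the midpoint, and among equal
maxima the lowest cut wins). The p-value is obtained by **permutation** of
the expression labels (default 1000, seeded) rather than an asymptotic
improved-Bonferroni bound: at the sample sizes involved permutation is
exact in distribution, assumption-free, and reproducible bit-for-bit under
a fixed seed. Because the scan depends on expression only through ranks, the
whole procedure is invariant to strictly monotone transforms. p-values are
not corrected across candidates; the screen is reported per candidate. The
sample-size floor is a `min_n` parameter (default 10). Kaplan–Meier
estimation and the plain two-group log-rank test are delegated to
`lifelines`, which also serves as an independent cross-check of the scan in
the tests.

## Immune scores and subtypes

The MHC/CYT/CTL scores are plain means over their gene panels, computed on
the log2(RPKM+1) scale for consistency with the rest of the expression
pipeline (raw-RPKM means would be dominated by the highest-expressed panel
member). Consensus clustering follows the conventional recipe: 100
resamples at 80% subsampling, k-means as the base clusterer, consensus
matrix = co-assignment frequency among co-sampled pairs, k ∈ [2,6] chosen
by the largest relative change in the area under the consensus CDF (the
k = 2 area counts as its own change), final labels by average-linkage
clustering of the consensus dissimilarity. All internals are configurable
and seeded. A run is flagged unstable when fewer than half the consensus
entries are near 0 or 1. Wilcoxon rank-sum comparisons are exact (exhaustive
permutation) when both groups have ≤ 10 samples and tie-corrected normal
otherwise; with more than two subtypes, all pairwise comparisons are
reported uncorrected, with correction left to the caller. Tumor mutation
burden is consumed as a per-sample count supplied with the cohort; the
package does not call mutations.

## Synthetic cohorts

The generator emulates the statistical regimes the analysis assumes, not
array chemistry:

- **Methylation**: each lncRNA has a baseline mean β drawn from Beta(2,3)
  (right-tilted toward the unmethylated side, as promoter CpGs tend to be);
  per-sample probe values are Beta-distributed around that mean with
  concentration κ = α+β = 30, giving per-sample β scatter of roughly 0.07–0.1
  — values in (0,1) by construction. Planted effects shift the tumor-group
  mean by Δβ while preserving κ; baselines of planted features are
  re-anchored (deterministic affine squeeze) into the window where the shift
  stays inside [0.05, 0.95], and an infeasible shift is a validation error
  naming the effect. Missingness is zeros at rate 0.05, independent.
- **Expression**: log2(RPKM+1) = baseline U(3,7) + Gaussian noise (σ = 0.5);
  coupled lncRNAs add slope × (promoter β − baseline mean) with slope −8,
  so a Δβ of 0.25 moves expression by 2 log2 units — a linear
  methylation→expression model, the simplest that produces the
  Pearson-detectable correlations the screen assumes. The baseline range is
  set so the strongest planted down-coupling cannot clip expression at zero.
- **Targets**: background lncRNA–miRNA and mRNA–miRNA edges are independent
  Bernoulli(density 0.02); planted ceRNA pairs receive n_shared dedicated
  miRNAs on both sides, and their mRNA partner tracks the lncRNA with a
  planted Pearson r. One target map is shared by all cancers.
- **Survival**: exponential event times; the hazard multiplies by the
  hazard ratio (default 3) for samples above the median expression of each
  planted prognostic lncRNA; censoring times are uniform on (0, H) with H
  solved by bisection so the expected censored fraction equals the
  configured rate (default 0.3) — this keeps `censoring_rate`
  interpretable while staying within the uniform-censoring design.
- **Subtypes/TMB**: tumor samples split evenly into subtypes; the key
  lncRNAs carry a mean-centered expression shift between subtypes (centered
  so the tumor-vs-normal DE truth is unaffected), and mutation counts are
  Poisson with per-subtype means (2, 8).

Identical config + seed reproduces a cohort bit for bit (a fixed
`SeedSequence` spawn tree, one stream per concern). The truth object records
every planted DM/DE/NClnc label, ceRNA pair, prognostic lncRNA, and subtype
so downstream recovery is scoreable.

What the generator does **not** model: probe-level chemistry (type I/II
bias), batch effects, copy-number confounding, tumor purity, miRNA
expression, or correlated censoring. Passing the recovery tests therefore
shows that the pipeline's logic and statistics behave as designed under its
own assumptions — not that those assumptions hold on any particular real
cohort.

## Reference study design and problem sizes

`three_cancer_demo_config` is the package's reference design: 3 cancers,
50 tumor / 20 normal samples each, 200 lncRNAs (3 promoter probes each),
100 mRNAs, 150 miRNAs; five lncRNAs planted up-methylated and coupled in all
cancers (the common set), one direction-mixed triple per cancer (the
specific sets), three planted ceRNA pairs, one prognostic lncRNA per cancer
at hazard ratio 3. A noise-free variant (κ = 4000, expression σ = 0.05, no
missingness) exists to demonstrate exact recovery of the planted set
algebra. The validation harness runs recovery at 10–20 seeds, null
calibration at 2,000 features × 25–50 replicates, the cut-point oracle at
50–100 datasets of n = 50, and null permutation uniformity at 100–200
replicates of 199 permutations — sizes at which every Monte-Carlo margin
used in the assertions is comfortably stable on a single CPU.

## Known limitations

- The two-group design has no covariates, batch terms, or paired structure.
- The specificity definition is sensitive to the set of cancers analysed:
  adding a cancer can only shrink specific sets.
- Permutation p-values are granular at 1/(B+1); screens at very small α
  need a larger permutation count.
- Consensus clustering on two features is a deliberately low-dimensional
  subtype model; with near-overlapping subtypes the CDF delta-area rule
  (like all consensus k-selection rules) can be unstable, which the
  `stable` flag surfaces but does not fix.
- The immune panels are fixed gene lists; absence of any panel gene is a
  hard error rather than a renormalised mean, so partial panels must be
  handled upstream.
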