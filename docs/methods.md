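# Methods

This note documents the models, defaults, and design choices behind
stressomics, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Behavioral phenotyping

The social interaction (SI) ratio is 100 × (time in the interaction zone
with a social target present) / (time with it absent); both trials last
150 s. SI ratios are right-skewed, so all location/scale arithmetic is done
on natural-log ratios:

* **Outliers** are log-ratios more than 3 interquartile ranges from the
  log-median, flagged two-sided and removed before classification. A zero
  IQR (degenerate but legal input) flags nothing.
* **The susceptible/resilient border** is exp(mean − SD) of the control
  group's log ratios, back-transformed to the percent scale for reporting.
  The scale of the mean − SD arithmetic is a genuine design choice (the
  log scale matches the transformation used to normalize the data, and
  back-transformed borders land in the 70–110% range typical of reported
  strain borders); mice exactly *at* the border are labeled resilient —
  only ratios strictly below it count as social avoidance.
* **Strain comparison** uses the Pearson chi-square on the 2×2
  strain × phenotype table, 1 df, without Yates continuity correction
  (group sizes here make the correction immaterial and the uncorrected
  statistic is the conventional choice at these counts).
* **Body weight** outliers use the modified Z-score, 0.6745 (x − median)/MAD
  with the conventional 3.5 cutoff; a zero MAD falls back to flagging
  nothing, with a warning, rather than erroring on constant series.
  Trajectories are reported per day as percent change from the day-1
  baseline — the natural reading of a "percentage of original body weight"
  summary.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular data set.

**Cohorts.** Control SI ratios are log-normal; defeated mice are a mixture
of a susceptible and a resilient component at a specified fraction, shifted
on the log scale by −1.0 and +0.3 respectively (≈3.7 control SDs below and
1.1 above the control mean at the default SD of 0.27). The shifts place the
two components clearly on either side of the mean-minus-one-SD border, so
the mixture weight is recoverable by the classifier — a deliberate propery
of the generator, since parameter-recovery tests are meaningless when the
components straddle the border. Default strain parameters encode the
two-strain design: a resilient-leaning strain (30% susceptible, 112
defeated + 56 controls) and a susceptible-leaning strain (89%, 70 + 56),
with control log-means anchored so the implied borders are 76.49 and 105.99
on the percent scale. Interaction-zone times are back-computed from drawn
ratios with a 30 s no-target time (rescaled when the implied target time
would exceed the 150 s trial), so `compute_si_ratio` reproduces the drawn
ratio exactly.

**Counts.** Sequencing counts are negative-binomial — the standard bulk
RNA-seq noise model — with gene-wise baseline means drawn log-normally
(log-mean log 100, log-SD 1), per-sample library-size factors uniform on
[0.7, 1.3], and additive log2-scale batch shifts (location only, matching
the location-only batch adjustment downstream). Planted gene sets shift the
log2 mean of member features by the set's effect size times a per-strain
sign in the affected phenotype groups; opposite signs between strains
reproduce the strain-divergent structure. Dispersion defaults to 0.1
(var = μ + 0.1 μ²), a mid-range value for bulk brain tissue.

What the generator does *not* emulate: gene–gene correlation, count
overdispersion heterogeneity across genes, composition effects beyond those
implied by the planted shifts, length/GC biases, and strain-specific
baselines. Passing tests therefore demonstrate correctness of the
statistical machinery under its own model assumptions, not robustness to
every artifact of real sequencing data. One such effect is visible even
here: because planted up-shifts enlarge realized library sizes,
CPM-normalized fold-change estimates of planted features carry a small
negative composition bias (≈0.05–0.1 log2 units at the defaults), exactly
as in real RNA-seq without compositional normalization.

**Proteomics.** Each sample is quantified against a pooled reference, so
the expected log2 heavy/light ratio is zero apart from planted effects and
biological noise (SD 0.25 log2 units). Three technical replicates per
sample; replicate variability is a per-protein property — a well-measured
bulk with linear-scale CVs uniform on [0.02, 0.15] and a 20% minority with
CVs on [0.35, 0.6], above the 30% inclusion cut. Unique-peptide counts are
likewise stable per protein (1 + Poisson(2)) with occasional one-peptide
replicate dropout. This bimodal structure gives the inclusion filter
(≥ 2 unique peptides in ≥ 2 of 3 replicates, CV < 30%) realistic work: a
protein's fate is decided mostly by its identity, with occasional
borderline cases, rather than independently per replicate.

**Interactions.** miRNA–target pairs carry an evidence-source count drawn
from a categorical distribution over {1, 2, 3}, mimicking annotation tools
that each either support a pair or not.

**Determinism.** One global seed per spec; each operation derives its own
substream (`SeedSequence([seed, tag])`), so outputs are bit-identical for
identical spec + seed, and adding an operation never perturbs another's
stream.

## Differential expression

Count matrices are CPM-filtered (keep features with ≥ 1 CPM in ≥ 6 samples
by default; the threshold is inclusive), transformed to
log2((count + 0.5)/(library + 1) × 10⁶), and optionally batch-adjusted by
per-feature, per-batch mean-centering that preserves feature grand means.
Scale (variance) batch effects are intentionally not adjusted; the
simulator plants location-only shifts and the adjustment matches.
Precision weights on the log-CPM values are not implemented: the moderated
t is the statistical core, and at the effect sizes and depths simulated
here the weights change little. Proteomics log-ratios are median-centered
per sample.

The moderated t follows the standard empirical-Bayes variance-shrinkage
construction: residual variances from the group-means model (pooled over
all groups present), hyperparameters (d₀, s₀²) by moment-matching
log s²_g to a scaled log-F distribution via digamma/trigamma identities,
trigamma inversion by Newton iteration (tolerance 1e-8, ≤ 100 iterations;
non-convergence falls back to d₀ = ∞ with a warning). Two numerical special
cases: features with zero residual variance are excluded from
hyperparameter estimation but still receive shrunk posteriors, and exactly
equal residual variances across all features (zero log-spread) yield
d₀ = ∞ with s₀² equal to the common value — the chi-square bias correction
is skipped there because it presumes sampling scatter that is absent, and
shrinkage correctly becomes a no-op. The implementation is cross-checked
against the reference R implementation (limma) on a fixture in the test
suite; agreement is to ~4 significant digits in the t-statistics.

Benjamini–Hochberg adjustment is the step-up rule
q₍ᵢ₎ = min_{j≥i} (m/j) p₍ⱼ₎ capped at 1. Note BH is *not* idempotent
(re-adjusting adjusted values can change them: [0.25, 1] → [0.5, 1] →
[1, 1]); the tests assert equivalence with the definitional computation
and rank preservation instead.

Fold changes are reported both as log2FC and as signed linear FC
(−2^|log2FC| for down-regulation), the sign convention of tabulated fold
changes in this literature. The DE rule is nominal P < 0.05 (strict) with
|FC| ≥ 1.2 (inclusive).

## Enrichment

The GSEA ranking metric is sign(log2FC) × (−log10 P), a standard choice
using both direction and significance; ties break by |log2FC| then feature
id so ranking is independent of input row order. P-values of exactly zero
are clipped to the smallest positive double before taking logs.

The preranked null draws random same-size member sets from the ranked
universe — the only null available for preranked input — with weight p = 1
by default. NES divides ES by the mean |ES| of same-sign null draws; a set
with an empty same-sign null at small n_perm gets an undefined NES and
PFDR 1, with a warning. FDR uses the pooled null-NES procedure, positive
and negative sides normalized and tallied separately. Permutation ES values
are computed vectorized from sorted hit positions (the running-sum extrema
can only occur at a hit or just before the next hit), verified against the
direct per-profile recursion in the tests. The unweighted (p = 0) statistic
satisfies ES(reversed list) = −ES up to exact ties between the positive and
negative extrema, which the rational step sizes of p = 0 make reachable;
the sign at such a tie is a tie-break artifact.

ORA is the upper-tail hypergeometric test of a DE set against each gene set
intersected with the universe; reports keep PFDR < 0.05 and truncate to the
100 most significant. GO-style term analysis is the same classic
hypergeometric test over a user-supplied term→gene GMT; no term-graph
decorrelation is attempted. The activation z-score is the unweighted signed
consistency sum over regulon targets divided by √n; it is approximately
standard normal under random directions but lattice-valued (step 2/√n).

## Integration

All convergence rules are set/threshold operations over a contrast grid
(dataset, strain, contrast) → table; the canonical grid is 2 strains ×
3 contrasts × 2 omics layers = 12 comparisons. Missing cells count as
non-significant, never as errors. "At least 25% of comparisons" uses a
ceiling on the comparison count. "More than two evidence sources" is
implemented as ≥ 3 with the threshold configurable. Cross-omics
identifiers are harmonized case-insensitively on gene symbol; unmatched
features simply fail to overlap. The cross-tissue correlation operates on
log2 fold changes by default, with the `on` column switchable to a mean
expression column — which quantity such correlations are computed on in
published analyses is often ambiguous, so both are provided.

## Pipeline and problem sizes

`run_pipeline` chains simulate → phenotype → de → gsea → integrate on a
synthetic two-strain study: one mRNA layer (2000 genes) and one protein
layer (600 proteins sharing the first 600 gene symbols), 8 samples per
group per strain, one planted 50-gene "mitochondrial" set (log2 effect 1.0,
opposite sign between strains, susceptible-vs-control), 20 random decoy
sets, GSEA at 500 permutations. These sizes give the planted set essentially
full power while a complete run, including all twelve moderated-t fits and
GSEA on all comparisons, stays in the tens of seconds on a single core;
they are scaled-down but structurally faithful study conditions, not a
claim about any particular experiment's depth. Both strains are simulated
in a single combined matrix so every sample has independent noise; the
strain sign flip lives in the planted signal.

## Known limitations

* No precision weights and no scale-component batch adjustment (see above).
* The GSEA null is gene-sampling, not phenotype permutation; its nominal
  P-values are granular at 1/n_perm per sign.
* The proteomics inclusion filter demands retention in every sample before
  a protein enters the DE matrix; with many samples this is conservative.
* The activation z-score ignores edge confidence weights; regulons are
  user-supplied signed target lists.
* Chi-square and binomial tests are asymptotic/exact respectively; no
  continuity corrections anywhere.
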