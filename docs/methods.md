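# Methods

## The problem

Single two-group RNA-seq contrasts of a regulator like MeCP2 are
underpowered and mutually inconsistent: effects are mostly below
two-fold, studies differ in tissue, cell fraction, sex and model class,
and overexpression (gain-of-function) models move transcription in the
direction opposite to knockouts. The pipeline here treats each
contrast's differential-expression summary (gene, log2FC, p, BH-FDR) as
the unit of evidence and asks which genes are perturbed consistently
across many contrasts, then characterizes that consensus set and
quantifies how replicate number limits single-study detection.

## Consensus core

Given contrast tables T_1..T_C and a significance level α (default
0.01), the masked fold-change matrix has entry

    M[g, c] = log2FC_gc  if FDR_gc ≤ α, else 0

over the union gene universe (a gene absent from a contrast is treated
as not significant there, which keeps support counts well defined).
Contrasts with no significant gene are dropped; gain-of-function
contrasts are negated so all columns share the loss-of-function
orientation (an involution — applying it twice is the identity). The
core is {g : support(g) ≥ k} with support(g) the number of non-zero
entries in row g. The direction split uses the mean of the *significant*
entries only: masked zeros mean "not significant", not "no change", and
averaging them in would shrink means toward zero by an amount that
depends on support. A mean of exactly 0 (a measure-zero event under any
continuous effect model) is labelled "up" and logged.

k can be given directly (default 4) or as a fraction of the contrasts
under analysis. A fraction is converted with round-half-down floored at
1: 10% of 43 contrasts gives k = 4 (the canonical operating point),
while 10% of 3 contrasts gives k = 1, so metadata sub-cores (per cell
fraction or tissue) remain usable on small subsets.

## Composition and position

Gene sets are summarized over eight broad annotation categories
(protein-coding, lncRNA, other ncRNA, pseudogene, small RNA, IG/TR,
TEC, other); genes missing from the annotation go to an "unannotated"
bucket with a warning so counts always sum to the set size.

For positional structure, genes on one chromosome are ordered by TSS
and encoded 6 (core-up), 3 (background), 0 (core-down); background
genes are drawn without replacement from non-core genes in equal number
to the core genes on that chromosome, with a stated seed. The track is
segmented by a simplified circular binary segmentation: the candidate
arc maximizing the pooled two-sample t statistic against its complement
is tested by permuting the interval's levels (default 1000 draws) and
accepted when the permutation p ≤ 0.01, recursing on the pieces while
intervals are at least twice the minimum segment length (default 5).
Linear mode (default) tests single change points; `circular=True`
enumerates every interior arc against its wrapping complement. A
perfect split (both sides constant, means differing) has infinite t and
is the strongest candidate; a constant interval has no defined t and is
never split. This is a deliberate simplification of the published CBS
family (no hybrid pruning or undo steps): the target use case is
detecting one contiguous elevated stretch, and the permutation max-t
test is exact for that question. Segment coordinates are reported as
1-based inclusive [first TSS, last TSS]; a `--bed` flag converts to
0-based half-open.

Tie handling: equal TSS values are ordered by gene id in the sort key
only; reported positions are unmodified.

## Pre-ranked enrichment and overlap

Ranking score: s_g = −log10(max(FDR_g, 1e−300)) × log2FC_g, sorted
descending with lexicographic gene-id tie-break (deterministic
permutation null; the clamp keeps scores finite when adjusted p-values
underflow, as real DESeq2 output does). Gain-of-function harmonization
is applied by negating ranking scores rather than flipping the final
NES: the two are sign-equivalent for ES and the ranking-level inversion
is deterministic end to end.

The enrichment score walks the ranked list adding |s|^w / Σ_hits |s|^w
at set members (w = 1 by default, the pre-ranked default) and
subtracting 1/(N − n_hits) elsewhere; ES is the signed maximum
deviation of the running sum, which provably returns to 0 at the end of
the list. A set covering the whole list has no misses and is rejected.
If every hit score is zero the hit steps fall back to 1/n_hits.

Significance uses n_perm random same-size gene-label sets (shared
between gene sets of equal size, so results do not depend on the order
sets are given): p = (1 + #{|ES_null| ≥ |ES|, same sign}) / (1 + #same
sign), NES = ES / mean(|ES_null| same sign), and FDR is the GSEA-style
ratio of null to observed tail fractions of sign-normalized scores,
clipped to [0, 1]. p can never be 0 (floor 1/(n_perm + 1)).

Overlap significance between two gene sets in an explicit universe uses
the two-sided Fisher exact test and the upper-tail hypergeometric
P(X ≥ overlap). The odds ratio is the sample cross-product ratio; a 0.5
Haldane correction is applied only when a zero cell makes the ratio
undefined (so disjoint sets report 0, not a corrected positive value).
The universe is a required argument — the choice between "all genes"
and "expressed genes" changes the answer and is the caller's to make.
Directional overlap intersects the contrast's up-DEGs with core-up (and
down with down); "both" ignores direction.

## DE test and down-sampling power

The caller is deliberately desk-scale, not a DESeq2 clone; it is used
self-consistently everywhere (full data and drawings):

- size factors: median across genes of count / geometric-mean ratios,
  using genes positive in all samples (positive-count fallback
  otherwise), rescaled so the factors' geometric mean is 1 — hence two
  identical libraries get (1, 1) and an exactly doubled library
  (1/√2, √2);
- expression filter: count ≥ 10 in at least half the samples (both
  knobs exposed; the source wording admits other readings);
- dispersion: pooled within-group moment estimate
  (var − shot-noise)/mean² floored at 1e−8, then shrunk toward a fitted
  a0 + a1/mean trend by a log-space weighted average with a prior
  weight of 20 pseudo-samples — with 2×10 samples the gene-wise
  estimate and the trend contribute about equally, which is what brings
  the null type-I rate at p ≤ 0.05 into the nominal 3–8% band
  (verified by simulation in the test suite);
- Wald test: log2 ratio of group means with a 0.5 pseudocount (exactly
  0 for identical groups), delta-method SE from the NB variance of each
  group mean, normal two-sided p, BH over tested genes only.

The down-sampling experiment draws n samples per group without
replacement for n in {10..3}, re-normalizes within each drawing (size
factors are recomputed per drawing), re-runs the caller, and records
DEG counts at FDR ≤ 0.01 for each fold-change cutoff (a linear ratio r;
a gene counts when |log2FC| ≥ log2 r) plus the Rand index between the
drawing's DEG indicator and the full-data indicator over all genes.
Each (n, rep) pair gets its own RNG substream derived from the master
seed, so adding repetitions never perturbs earlier drawings. Fold-change
survival curves report the percentage of full-data DEGs with |log2FC| ≥
c over a cutoff grid and the first grid point where fewer than half
remain.

## Synthetic data: what it emulates, and what it does not

The multi-contrast generator plants 150 up + 120 down core genes among
5000, each significant (FDR drawn below 0.01) in a Bernoulli(0.6)
subset of 40 contrasts with signed ~N(0.6, 0.2) log2 fold changes, and
flips every true signal in two gain-of-function contrasts at generation
time — so the pipeline's inversion step must restore them. Background
genes are spuriously significant at 3% per contrast with sign-symmetric
effects, but each background gene's significant-contrast count is
truncated below 5% of the contrasts. The truncation is what makes
"recovery of the planted truth" well posed: an untruncated background
gene significant in ≥ k contrasts would *satisfy the core definition*,
and counting it as a false positive would measure the generator, not
the method. FDR values are Uniform(1e−6, α) when significant and
Uniform(α, 1) otherwise — the pipeline only thresholds FDR, so only the
masses on either side of α matter.

The count generator uses log-normal baselines (median 100, log-sd 1.7),
a declining dispersion trend a0 + a1/μ (0.02 at the median baseline,
asymptote 0.005 — the brain-tissue inbred-mouse range) with
inverse-gamma gene noise, log-normal size factors (log-sd 0.1), and 15%
DE genes whose |log2FC| is exponential with mean 0.5: most effects are
below two-fold and many are subtle, which is precisely the regime where
fold-change cutoffs interact with sample size — deep designs detect
small-effect genes that a 20% fold-change cutoff then removes, so the
FC > 1.2 power curve flattens while the any-FC curve keeps rising.

What the generators do not emulate: batch effects and study-level
correlation between contrasts (each contrast's noise is independent),
annotation–core dependence (biotypes are assigned independently of core
membership, so no composition spike is expected in simulation), gene
length or GC structure, and library-composition bias beyond a scalar
size factor. Passing tests therefore demonstrate correctness of the
statistics and recoverability under the planted model, not robustness
to confounding in real archives.

## Problem sizes and numerical choices

Simulated fixtures run at 5000 genes × 40 contrasts for the core
analyses, 2000 genes × 40 samples for the power analysis (20
repetitions per sample size), 200-gene tracks with 300–1000
permutations for segmentation, and 200–1000 permutations per
enrichment test — sizes at which every analysis completes in seconds
while leaving the planted structure clearly resolvable. Determinism:
every stochastic routine takes an explicit seed and is reproducible
bit-for-bit; the segmentation consumes its RNG in recursion order, so
identical inputs and seeds give identical segment trees. Degenerate
inputs are errors, not silent answers: empty gene sets, universes, or
contrast lists; gene sets covering a whole ranked list; groups with
all-zero libraries; tracks with no genes on the requested chromosome.

## Known limitations

- The NB Wald caller is anti-conservative for very small groups (n = 2)
  where moment dispersions are dominated by the trend; the power
  analysis is comparative across n, not an absolute power calculator.
- The simplified CBS reports the p-value of the split that created each
  segment rather than a per-segment confidence measure, and does not
  prune or merge adjacent segments.
- GSEA-style FDR with few gene sets is coarse (it pools few observed
  scores); p-values and NES are the primary outputs.
- Ortholog joining consumes pre-computed best-match tables; when two
  source genes map to one target the more significant row is kept — a
  documented choice where upstream tools are silent.
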