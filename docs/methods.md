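# Methods

## The comparison being modeled

Two related species are sampled at three consecutive embryonic stages
(PC = prawn-chip/blastula, G = gastrula, S = sphere/early larva), three
biological replicates per stage, bulk RNA-seq counted at the gene level.
The analysis asks how much of each species' stage-resolved transcriptional
program is conserved across the species boundary: which orthologs are
differentially expressed in both species, whether they move at the same
stage, whether they occupy the same coexpression archetype, how duplicated
genes (in-paralogs) diverge, and whether a bait gene's correlation
neighborhood is rewired between species.

## Differential expression model

Counts are modeled as negative binomial, `K ~ NB(mean μ, dispersion α)`
with `Var K = μ + αμ²`. The test implemented here is a closed-form Wald
test rather than a GLM fit:

- Size factors are median-of-ratios: per sample, the median over genes
  (with all-positive counts) of the count divided by the gene's geometric
  mean across samples. The median is taken on the ratio scale, not the
  log scale — the two differ for even gene counts.
- Per-gene dispersion is method-of-moments on size-factor-normalized
  counts with stage means removed (pooled within-stage variance, df =
  samples − stages): `α̂ = max((s² − m)/m², 1e-8)`, then shrunk halfway
  on the log scale toward the across-gene median. The shrinkage stabilizes
  the 6-df raw estimates; the floor keeps Poisson-like genes finite.
- `log2FC = log2((m_later + ½)/(m_earlier + ½))` with group means of
  normalized counts; the ½ pseudocount bounds the statistic for
  zero-count groups. The standard error comes from the delta method:
  `Var log2(m + ½) ≈ Var(m) / ((m + ½) ln 2)²` with
  `Var(m) = (m + αm²)/n`. Two-sided normal p-values, BH step-up
  adjustment (hand-written; the test suite checks it against statsmodels
  to 1e-12).
- DEG rule: `|log2FC| ≥ 1` and `p_adj < 0.05`. The fold-change boundary
  is inclusive and the FDR boundary exclusive by default; both modes are
  configurable because reasonable conventions differ. Genes with zero
  counts in both groups are reported with p = p_adj = 1 rather than
  dropped, keeping all tables aligned.

This is a deliberate simplification of a full NB GLM with fitted
dispersion trends and LFC shrinkage: every quantity is closed-form and
independently recomputable, which is what the oracle tests exploit.
A consequence is that log2FC estimates are not shrunk, so low-count genes
have noisier fold changes than a shrinkage estimator would report.

## Coexpression archetypes

The clustering input is each gene's VST profile (`log2(normalized count
+ 1)`) standardized to mean 0, sd 1 across the species' nine samples;
replicate-level values are used rather than stage means so within-stage
variability informs the distances. Zero-variance genes are flagged and
excluded. K-means uses k-means++ with 10 restarts and up to 1,000
iterations; the best-inertia restart is kept and the whole procedure is
deterministic given the seed.

With k = 6 the clusters are mapped bijectively onto the archetypes
C1 (up in PC), C2 (PC+G), C3 (G), C4 (G+S), C5 (S), C6 (PC+S):
centroid stage means are z-scored and scored against z-scored binary
templates by cosine similarity, and the assignment maximizing total
similarity is chosen (Hungarian algorithm; deterministic tie-break).

The elbow curve reports best-of-10 within-cluster SS for k = 1..k_max.
The suggested k is the argmax of the second difference of log(WSS):
raw second differences peak at small k on any steeply decreasing curve,
whereas the relative (log-scale) curvature correctly flags the planted
cluster count on labeled data, so the log form is used.

## Ortholog and paralog comparisons

Orthogroups come from OrthoMCL-dialect groups files. Relationship classes
are defined per group for the species pair (A, B): one2one (1 gene each),
one2many_A (many in A), one2many_B (many in B), many2many. All
cross-species comparisons use one-to-one pairs.

- A species-level DEG is a gene in the union of DEGs over both
  comparisons.
- "Up at G" means `up_stage = G` in at least one comparison — the G side
  of PC vs G or of G vs S.
- Synchrony (per comparison, among pairs both-DE in it): same stage iff
  both up-stages are equal and defined; the percent is rounded to the
  nearest integer. Archetype-overlap percents are reported to one
  decimal, matching the conventions of published summary tables.
- Cluster-overlap pairs with an unclustered member are excluded from the
  6×6 matrix and counted separately; the same-archetype percent divides
  the diagonal total by the both-DE pair count.

Paralog pairs are classified per comparison into P1/P2/P3 (both / exactly
one / neither DE) and into Pk1/Pk2/Pk3 by cluster membership. "Similar
pattern" means identical up-stage (P1) or identical archetype (Pk1).
Pair correlations are Pearson over the nine replicate-level VST values —
stage-mean profiles have three points and make correlations nearly
degenerate. Pairs with a constant profile have undefined PCC and drop out
of threshold fractions' denominators.

## Bait networks

A bait's PCC profile is computed against every gene of its species
(within-species only; cross-species comparison happens at the family
level). Two thresholding modes: empirical quantiles of the profile at
ranks 0.05/0.95 (linear interpolation between order statistics, so
results are bit-reproducible), or a fixed |PCC| > 0.8. Both are provided
because percentile-based tools and fixed-threshold figures are both in
common use; the percentile mode requires at least 20 finite correlations.
Partners are grouped into families by orthogroup (singletons otherwise).
Two networks are compared on shared families; a family's sign is
positive/negative if its edges agree and "mixed" otherwise, and
concordance means equal signs. Same-species comparisons (isoform baits)
are allowed and flagged.

## Enrichment

One-sided hypergeometric upper-tail tests per annotation term, BH over the
tested terms. Terms with zero query hits are not tested, which sets the
BH denominator — stated explicitly because it changes adjusted p-values.
Term sets are flat: no ontology-hierarchy propagation, so parent terms
receive no implicit counts. The population defaults to the annotated gene
universe supplied by the caller.

## Synthetic data generator

`syndata` emulates the study design: `n_orthogroups` orthogroups drawn
from the relationship mix (default 0.86/0.10/0.02/0.02), archetype labels
from `archetype_probs` (default: each of C1–C6 at 0.10, flat at 0.40 so
not all genes are DE), NB counts with shared dispersion (default 0.05)
at 3 replicates, baseline means log-normal (log-mean 4, log-sd 1, i.e.
median ≈ 55 counts), planted up-states multiplying the mean by
`2^effect_log2fc` (default 2.0) at the archetype's stages, and per-sample
depth factors log-uniform in [0.7, 1.4]. Transcript lengths are
log-uniform in [500, 5000] nt (used only for TPM). Gene ids follow the
`species|gene` convention; transcript ids `gene.k` support the isoform
census (default: 15% of genes multi-isoform with a geometric tail).

Conservation planting: within each one-to-one ortholog pair and each
in-paralog pair, flatness is coupled (both flat or both non-flat); a
non-flat pair is conserved with the planted probability, in which case
both genes share an archetype, and otherwise the second gene receives an
explicitly *different* archetype. This makes the same-archetype fraction
among non-flat pairs equal the planted fraction exactly in expectation —
no chance-agreement correction is needed in recovery tests. Defaults:
ortholog conservation 0.15, paralog conservation (0.50, 0.85) for the
two species, echoing the asymmetry reported between the two corals.
In-paralog pairs are standalone within-species gene pairs emitted as a
separate pair list (default counts (1500, 500), a scaled-down emulation
of the study's ~11k/~2k pairs sized for recovery power at desk scale).

Annotation: each gene receives `go_terms_per_gene` of `n_go_terms` flat
terms; the first term's sampling weight is multiplied by
`enriched_term_archetype_bias` (default 4) for genes of one designated
archetype (default C3), planting a known enrichment signal.

What the generator does **not** emulate: gene-length bias in counts,
per-gene dispersion trends, correlated genes within pathways beyond the
archetype structure, unbalanced library sizes beyond ±40%, mapping
artifacts, or isoform-level expression (isoform ids exist, counts are
per gene). Passing recovery tests therefore demonstrates correctness of
the algorithms under the stated model, not robustness to every real-data
pathology.

## Quartile abundance tables

Per stage, transcripts with positive mean TPM over the stage's replicates
are ranked on the pooled coding+noncoding distribution and split into
four contiguous near-equal bins (ties broken by gene id; pooled bin sizes
differ by at most one). Each class's bin counts are tested against the
uniform expectation (total/4) with a chi-square goodness-of-fit, df = 3,
no continuity correction. Because bin sizes are fixed by the pooled
ranking, the class counts are hypergeometric rather than multinomial and
the test is slightly conservative — the null calibration in the test
suite measures a rejection rate well under the nominal 5%.

## Pipeline and reproducibility

The CLI runs each stage against an output directory; every stage appends
a manifest entry (parameters, seed, SHA-256 of each output file), and a
missing upstream output fails with the name of the stage to run first.
All randomness flows from the single root seed through named substreams
(hashed stage names → spawn keys), so `run-all` twice with the same seed
and config produces byte-identical outputs; the acceptance script checks
this, and derived seeds stay below 2^31.

Default problem sizes (3,000 orthogroups, ≈ 3,600/3,600 orthogroup genes
plus 2×1,500/2×500 paralog genes per species) run the full pipeline in
seconds while leaving every recovery estimate well-powered; calibration
loops use 1,000 replicates of 150-transcript stages and a ~1,000-gene
null dataset.

## Known limitations

- The Wald test with n = 3 per group relies on a normal approximation;
  it is mildly anticonservative for very low counts, which the DEG
  fold-change threshold largely masks (measured null rates are far below
  nominal).
- The archetype bijection is defined only for k = 6; other k values
  cluster but carry no archetype labels.
- BH adjustment is not idempotent (re-adjusting adjusted p-values
  changes them); adjusted values are computed once from raw p-values.
- Network sign concordance treats a "mixed" family (edges of both signs)
  as its own sign; alternatives (majority vote) would change borderline
  comparisons.
- GO terms are flat labels; without hierarchy propagation, enrichment of
  specific terms does not surface at ancestor terms.
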