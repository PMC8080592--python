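# Methods

This note documents the models and procedures epiflock implements, the
parameters that matter, the synthetic data generator's design, and the
numerical choices made where the design was genuinely open.

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)`; conversion
happens only at I/O boundaries (GTF is 1-based inclusive, BED is already
half-open). The TSS of a plus-strand gene is `start`, of a minus-strand gene
`end − 1`; unstranded features fall back to `start` with a logged warning.
Promoters are the `upstream_bp` (default 2000) bases immediately 5′ of the
TSS, clipped at chromosome bounds. CGI shores, when not supplied, are
derived as 2 kb flanks of the CGIs minus the CGIs themselves; the shore
width is a parameter because no single community definition exists.
Interval queries run on per-chromosome interval trees and are verified
against a brute-force scan in the tests.

## lncRNA identification

The cascade keeps transcripts that satisfy **all** of:

| filter | rule | default |
|---|---|---|
| structure | exon count ≥ `min_exons` and summed exon length > `min_length` | 2 exons, 200 bp (strict >) |
| known overlap | no ≥ 1 bp exonic overlap with an annotated coding exon | both strands |
| expression | max FPKM across samples ≥ `min_fpkm` | 0.5 (inclusive) |
| coding potential | called non-coding by every available predictor | all of CNCI/CPC/Pfam/PhyloCSF supplied |

Because the filters are conjunctive predicates, the surviving set is
independent of stage order (a property test permutes the cascade). Three
choices were open and are exposed as parameters: the strandedness of the
known-exon overlap test (`both` by default — the conservative reading, since
a sense or antisense exonic overlap both compromise the assembly evidence);
"FPKM" for the detectability filter meaning the maximum over samples (the
permissive standard for detectability); and the predictor set for the
consensus (all supplied predictors must agree; a missing predictor column is
ignored with a warning rather than failing the cascade).

Survivors are classified with precedence antisense > intronic > intergenic:
antisense if any exon overlaps a coding gene's span on the opposite strand
(gene-span rather than exon-level overlap, matching common lncRNA
classifiers), intronic if the whole span is contained in a same-strand
coding gene, intergenic otherwise. Classification is total and exclusive.

## Methylation

**Levels.** ML = m/(m+u) per cytosine; windows and features pool raw counts
first and take one ratio (so the estimate is coverage-weighted and invariant
to how records are split). The non-conversion rate r is the pooled
methylated fraction over the unmethylated lambda spike-in; the corrected
level (ML − r)/(1 − r) is clamped to [0, 1] because sampling noise can put
ML below r. The correction is monotone in ML (property-tested), applied
after pooling.

**Site calling.** Per covered site, a one-sided binomial test of
H₀: p = r against p > r (methylation must exceed conversion noise), with
BH adjustment within each context (CG/CHG/CHH have radically different
baselines, so pooling contexts in one BH family would let the CG signal mask
non-CG calls); flagged at adjusted p < 0.05.

**DMR calling.** The caller compares two groups' pooled per-site counts
with a two-sided Fisher exact test, BH-adjusts within context, merges
consecutive significant sites whose level difference has a consistent sign
and whose gaps are ≤ `max_gap` (200 bp), and keeps merged runs with at least
`min_sites` (3) sites and a pooled |ΔML| ≥ `min_delta` (0.1, typical WGBS
practice). Direction is hyper when group B exceeds group A. This is a
deliberately simple, dependency-free desk-scale caller: it has no
beta-binomial dispersion shrinkage or smoothing, so it treats replicates as
poolable and will be anti-conservative when biological replicate variance is
large relative to binomial noise. Externally called DMRs can be imported
from BED to bypass it. The Fisher test itself is a vectorized
conditional-hypergeometric implementation of the minimum-likelihood
two-sided rule, verified against `scipy.stats.fisher_exact` to machine
precision in the tests (a per-site scipy loop is ~500× slower at
genome scale). CG sites on opposite strands are not merged; merging halves
the resolution and the caller gains nothing from it at simulated depths.

**DMR genes.** A gene is a DMR gene when any DMR overlaps (≥ 1 bp) its body
(TSS to TES) or 2 kb promoter; the overlap location (body/promoter/both) is
recorded. Verified against a brute-force double loop.

## Differential expression

A Welch t-test on log2(FPKM + 1) between the two groups of a contrast
(BM-BF, NM-NF, NM-BM, NF-BF; B = control, N = treated, M = muscle,
F = adipose), BH-adjusted, significant at adjusted p < 0.05. This is a
deliberate stand-in for a full count-model DE engine: the network logic
downstream needs DE labels and directions, not any particular DE model, and
externally computed DE tables in the same shape can be supplied instead.
Features with zero variance in both groups get p = 1.

## Target prediction

Co-location pairs a lncRNA with every gene whose span intersects the window
100 kb up/downstream of the lncRNA (strand-agnostic, anchored on the
lncRNA); distance is 0 for overlap, otherwise the gap. Co-expression tests
all lncRNA × gene pairs: Pearson correlation with a two-sided t-test on
n − 2 df, BH over the whole tested family, kept when |PCC| > 0.95 (strict)
and adjusted p < 0.05. Constant features are dropped (correlation
undefined), never treated as zero.

Correlation is computed on **log2(FPKM + 1)** by default. FPKM is
approximately log-normal, and the Pearson correlation of two log-normals is
bounded well above −1 (with latent correlation −0.99 and ~0.7 ln-units of
spread the raw-scale correlation is only about −0.6), so screening raw FPKM
at a ±0.95 threshold is structurally blind to negative co-expression. On
the log scale the threshold treats both signs symmetrically.
`log2_transform=False` restores raw-scale screening.

The final target set is the union of the two evidence streams keyed by
(lncRNA, gene), with evidence `both` on overlap.

## Enrichment, network, modules

Enrichment is the upper-tail hypergeometric probability P(X ≥ k) for k query
genes in a K-gene term, n query genes in an N-gene universe, BH across
terms, enriched at adjusted p < 0.01; depletion is not tested. Annotation
sets are flat term → gene TSVs with no ontology-graph propagation.

The regulatory network keeps edges (l, g) where l is a DE lncRNA, g is a DE
gene, (l, g) is a predicted target pair, and g is a DMR gene; isolated nodes
are dropped, node degree is stored as an attribute, exports are SIF +
GraphML + a node-attribute TSV (lossless round-trip tested).

Regulator overlap between two genes reports
(100·|A∩B|/|A|, 100·|A∩B|/|B|), rounded half-up to two decimals.
Co-regulated modules: genes are linked when **both** pairwise shares are
≥ `share_min`, modules are connected components with ≥ 2 genes, and the
shared regulator set is the intersection over the module. "Regulated by the
same lncRNAs" is exact set equality at `share_min = 1.0` (where modules are
precisely the equivalence classes of regulator sets, property-tested); the
default 0.75 also admits strongly-overlapping pairs of the kind observed in
real networks (shares of 76–89%).

## Synthetic data generator

The generator emulates the 2 tissue × 2 treatment × 3 replicate design
(12 samples) at desk scale. Defaults: 2 chromosomes × 120 kb, 30 coding
genes, 40 lncRNA candidates, mean per-cytosine depth 20×, CG methylation
baseline 0.706, CHG/CHH baseline 0.0027, non-conversion rate 0.005, 8
planted CG DMRs of 800 bp with ±0.25 level shifts in treated adipose, 10
planted lncRNA–gene pairs at latent correlation 0.99, 12 planted DE features
at |log2FC| = 4, and a 6 kb unmethylated lambda spike-in. The genome sizes
are the package's own desk-scale choice — large enough that every region
class, lncRNA class and filter fail mode is populated and DMRs contain
40–60 CpGs, small enough that the whole study simulates in seconds. All
randomness flows from one seed through fixed per-stage streams; the same
seed reproduces every output file byte-for-byte (tested).

Specifics worth knowing:

- **Candidates**: every identification-filter fail mode is planted in known
  numbers (single-exon; exactly 200 bp total; ≥ 1 bp coding-exon overlap;
  sub-threshold expression; a coding call from ≥ 1 predictor), each
  constructed to pass all *other* filters, so the per-stage removal counts
  are known exactly. Passing candidates cycle through the intergenic /
  intronic / antisense placements; every second gene is built with two
  terminal exons around one large intron to guarantee intronic/antisense
  placement space.
- **Expression** is log-normal with a per-feature tissue effect (σ = 2 log2
  units) giving within-tissue sample correlations well above between-tissue
  ones, and a treatment effect for the planted DE set. Planted co-expressed
  pairs are driven by a shared standard-normal latent factor
  (y = √ρ·z + √(1−ρ)·ε per member), which fixes the expected log-scale
  correlation at ρ without distorting marginals. Planted-pair features get
  no design effects (a tissue effect would decorrelate the pair);
  low-expression fail-mode candidates get none either (a large tissue effect
  could push them over the 0.5 FPKM threshold and falsify the bookkeeping).
  DE-planted lncRNAs sit at an mRNA-like baseline (log2 FPKM ≈ 4) so a
  downward 16-fold change stays above the pseudocount floor and remains a
  real, detectable expression difference.
- **Bisulfite counts**: per site and sample, depth ~ Poisson(20) and
  methylated counts ~ Binomial(depth, p + (1−p)·r); p is the context
  baseline, shifted inside planted DMRs for treated samples of the DMR
  tissue. The lambda chromosome has p = 0, so its pooled methylated
  fraction estimates r. Contexts are assigned from the simulated reference
  by the same rules the analysis uses (CG / CHG / CHH with H ∈ {A,C,T},
  minus strand read on the reverse complement).

What the generator does **not** emulate: biological replicate-to-replicate
methylation variance (counts are binomial given the group mean, which is
exactly the regime where pooled Fisher testing is correct — real data with
overdispersed replicates needs a shrinkage caller), read-level artifacts
(M-bias, mapping errors, PCR duplicates), assembly uncertainty in transcript
models, expression–methylation coupling (planted DMR genes are not forced
to be DE), and realistic CpG-island sequence composition (CGIs are placed
as promoter intervals, not GC-rich sequence). Passing recovery tests
therefore demonstrates correctness of the statistical machinery under its
stated assumptions, not robustness to these real-data features.

## Degenerate inputs and tie-breaks

Zero-coverage cytosines are dropped with a logged count (ML undefined).
Zero-variance expression features are excluded from correlation testing and
get p = 1 in DE. Query genes outside the enrichment universe are dropped
with a warning. An empty network exports valid empty files. Promoters
flush against a chromosome edge are `None` rather than empty intervals.
Duplicate cytosine positions in a DMR input are an error (pool counts
first). Overlap shares are rounded half-up so printed values like 76.09%
reproduce exactly.
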