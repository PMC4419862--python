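# Methods

## Model and assumptions

middascan detects secondary-metabolite biosynthesis (SMB) gene clusters
from the joint behaviour of *physically consecutive* genes under a
producing vs non-producing condition contrast. The method assumes:

1. Genes of a functional SMB cluster occupy consecutive positions on one
   contig and are transcriptionally co-regulated.
2. Background genes are not positionally organized with respect to their
   regulation, so the induction ratios of a random window of genes
   average to approximately zero.
3. After Z-scoring, per-gene induction ratios are roughly symmetric
   around zero, so window sums of background genes are approximately
   normal (a central-limit argument over near-independent terms).

The per-gene induction ratio is `m = log2((mean_num + c)/(mean_den + c))`
with replicate means and pseudocount `c`. The window statistic is the
sum of Z-scored m-values over each window of `ncl` consecutive genes
(windows never cross contig boundaries). Each window's M score is then
standardized against all windows of the same size (`Z_M`), and scored

    omega = -(Z_M)^d * ln(P),

`d` odd so that omega keeps the sign of `Z_M` (positive = induced in the
numerator condition, negative = repressed), and `P` the two-sided
standard-normal tail probability of `Z_M`. The moment term `(Z_M)^d`
amplifies deviation from the background distribution; the rareness term
`-ln P` further emphasizes windows of low occurrence probability.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `d` | 3 | moment order; must be odd and positive so sign(omega) = sign(Z_M). 3 balances amplification against numeric blow-up. |
| `ncl` range | 3–30 | known SMB clusters typically span ~10–30 genes; 3 admits minimal clusters such as the kojic-acid trio. |
| `pseudocount` | 1.0 expression unit | applied to both replicate means; keeps m finite on zeros without noticeably biasing expressed genes. |
| log base for m | log2 | makes m symmetric about 0, which the Z-score framing presumes; `ln` and raw-ratio modes exist for sensitivity checks. |
| `tail` | parametric | P from a standard-normal fit to the Z-scored M values. The empirical alternative is quantized at 1/#windows, which caps the rareness term for exactly the windows it must emphasize, so it is opt-in only. |
| P floor | 1e-300 | keeps ln P finite for extreme windows. |
| omega threshold | user-supplied | cut-offs are dataset-specific; `permutation_null` (gene-label shuffles of the m-vector, seeded) returns max-abs-omega quantiles to calibrate one per dataset. |
| `min_chain`, `max_gap` | 3, 2 | synteny chaining: minimum ortholog anchors per block and tolerated unpaired genes between consecutive anchors on each genome. |

t-values are Welch's unequal-variance statistic, computed by default on
log2(x + pseudocount) replicate values so t lives on the same log-fold
scale as m (replicate variances of expression data are heteroskedastic;
a raw-scale switch exists). Welch requires two replicates per condition;
with fewer, t is reported unavailable rather than guessed.

## Numerical and procedural choices

- **Population (1/N) standard deviations** everywhere a census is
  standardized (all genes, all windows): the vector is the whole
  population, not a sample.
- **Gene order** is by start coordinate, ties broken by gene id; strand
  recorded but ignored; overlapping genes are kept, not merged.
  Coordinates are 1-based inclusive (GFF3); BED input is converted on
  read.
- **Undefined m** (both means zero at pseudocount 0) is flagged and set
  to 0 — the post-centering mean — so window arithmetic stays aligned to
  gene order; flagged genes rank last in rank tables.
- **Degenerate statistics** (constant m-vector, single window, zero sd
  of M) raise a dedicated error rather than returning NaNs; the CLI maps
  it to exit code 3.
- **Call merging**: within one (CCC, ncl) track, significant windows
  sharing a gene merge transitively; the merged call's gene set is the
  window of maximal |omega| and the remaining genes are listed as
  extension candidates, reflecting that window-sum boundaries tend to be
  tight. Across ncl values of the same CCC, calls merge when one
  contains the other's peak gene, defined as the centre gene of the
  stronger call's peak window — one of several defensible conventions;
  chosen because the centre is the gene least sensitive to boundary
  jitter. Calls from different CCCs are never merged.
- **Rank tables** use competition ranking (ties share the minimum rank)
  so "ranked 1st" is unambiguous; display order breaks remaining ties by
  item id. Window scores are the arithmetic mean of the per-gene index;
  for m×a the per-gene products are averaged (not recomputed from
  window-mean m and a), keeping the window score linear in per-gene
  contributions.
- **Synteny chaining** is greedy left-to-right per contig of genome A:
  anchors extend a chain while gaps on both genomes stay within
  `max_gap`, the partner contig is unchanged, and partner ordinals move
  monotonically in the chain's orientation (fixed by its first step).
  Unpaired genes lying inside a block's span are labelled SB — they sit
  within a conserved block. Ortholog detection itself is out of scope;
  the input is a precomputed reciprocal-best pair table.

## The simulator

`synthetic_data` generates what the detector assumes: a genome of
ordered genes (fixed spacing, alternating strand), per-gene baseline
expression drawn log-normal (default median 100 units, sd-log 1.0),
multiplicative log-normal replicate noise (default sd-log 0.5), and
planted clusters of consecutive genes whose expression is multiplied by
a fold factor (default one 10-gene cluster at 8-fold) in designated
producing conditions only. The default design is 4 conditions of which 1
producing, 3 replicates each, 2,000 genes on one contig; a single
integer seed fixes placement, baselines and noise.

What the simulator does **not** emulate: count-based sampling noise
(values are continuous expression units, not reads), gene-length or
GC effects, correlated background co-expression (neighbouring
housekeeping genes sharing chromatin state), partial or leaky cluster
induction, and annotation errors. Passing the recovery benchmarks
therefore demonstrates the statistic's behaviour under its own model —
clean planted signal against independent log-normal noise — not
performance on real transcriptomes, where background co-expression
inflates the null tail and thresholds must be calibrated per dataset.

## Validation problem sizes

The test suite and the acceptance script use a 2,000-gene genome with
one 10-gene 8-fold cluster for recovery (100 seeds, one ncl), 200-gene
genomes for brute-force oracle equivalence, and 20 seeds for the
window-vs-gene ranking comparison; these sizes give stable statistics
while keeping a full run in tens of seconds on one CPU.

## Known limitations

- The parametric tail assumes the Z-scored M values are close to
  standard normal; datasets with many strong clusters shift the fitted
  centre and can underestimate deviations (visible as deflated omega for
  secondary peaks).
- omega thresholds do not transfer between datasets; always calibrate
  with the permutation null.
- The synteny module is a deliberately simple collinearity chainer for
  SB/NSB labelling, not a full genome-comparison tool: no many-to-many
  orthology, no inversions within a block, no similarity weighting.
- Expression input must be pre-normalized; the package performs no
  TMM/RPKM-style normalization.
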