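# Methods

`syndel` implements the computational stages of a block-deletion analysis in
a post-polyploid plant genome: finding retained syntenic blocks and dating
them by synonymous substitution rate, accounting for the content of deletion
intervals, predicting nuclease off-target sites for deletion guide RNAs, and
quantifying the transcriptomic consequences of a deletion at the paralogue,
orthogroup and coexpression-network level. Because the real analyses depend
on deposited sequencing data and a third-party network, every stage is
exercised on synthetic data whose generating parameters are known, so the
test suite checks parameter recovery rather than output identity.

## Synthetic genome

`generate_genome` tiles each chromosome into ancestral segments (default
15–40 genes; the real block-size distribution is only known through summary
statistics, so the range is exposed in `SimulationConfig`). Disjoint segment
pairs are joined as duplicate blocks; each pair survives for one polyploidy
event with that event's `retention_rate`. Within a retained block each gene
keeps its partner (an anchor pair) with probability `1 − fractionation_rate`
(default 0.4). Anchor Ks values are lognormal: for an event with mode *m*
and log-scale spread σ (`ks_sd`), draws use μ = ln *m* + σ², so the
distribution's mode is exactly *m* and the skewed cloud shape of empirical
Ks distributions is reproduced. The default events place a recent
duplication at Ks mode 0.8 and an ancient one at 2.0, echoing the
alpha/beta-versus-gamma split of Brassicaceae. Tandem duplicates (5% of
genes, partner within 3 ranks), TEs (0.3 per gene), lethality flags (10%)
and extra multigene families are planted independently. Genes carry both a
bp interval and a rank (gene-order index); chaining operates on ranks,
interval accounting on bp.

Every generator draws from its own stream keyed as `(seed, stream_id)`, so
adding a generator never shifts another's output and a fixed seed is
byte-reproducible.

What the generator does **not** emulate: sequence-level evolution (anchors
are positional, not alignment-derived), nested or overlapping duplications,
segmental-duplication mechanisms other than whole-block pairing, and
asymmetric subgenome fractionation. Passing recovery tests therefore show
that the detection and dosage machinery is correct under the stated
statistical model, not that it is robust to every artefact of real genomes.

## Syntenic blocks

`chain_anchors` is DAGChainer-style collinear chaining: per chromosome pair
and orientation, a longest-chain dynamic program admits chains whose
consecutive anchors differ by at most `max_gap_genes` ranks (default 20) on
both sides, keeps chains with at least `min_anchors` anchors (default 5),
peels the best chain off and repeats. The chain score is the anchor count
with no gap penalty (the original log-odds scoring is not reproducible from
the published settings); ties break to the leftmost (rank_a, rank_b) chain,
making output deterministic and input-order invariant. The
"five syntenic genes per 20-gene window" description is implied by these two
parameters and is not enforced as a separate sliding-window filter.
`merge_blocks` joins same-pair, same-orientation blocks separated by at most
`merge_gap_genes` (default 40 = 2 × the gap bound) on both sides, closing
the relation transitively, which makes merging order-independent and
idempotent; the full quota-align linear program is out of scope.

Block age uses the mode of the anchor Ks values, estimated by Gaussian KDE
(Silverman bandwidth) on a fixed grid 0–5 with step 0.005; degenerate
samples return their value directly. Classification into `alpha_beta`
versus `gamma` uses a caller-supplied boundary `alpha_beta_max` (inclusive
on the young side). No universal boundary exists — it depends on the
lineage's substitution rate — so the parameter is required at the API and
the pipeline default (1.2, between the two default simulated modes) is a
documented choice, not a biological constant. Conservation rate is defined
as anchors ÷ genes spanned by the block's A-side region. Tandem duplicates
are maximal same-family runs with at most `max_rank_gap` intervening genes
between consecutive members (default 10), closed transitively.

## Deletion regions

Intervals are 0-based half-open, so length = stop − start; the curated
coordinate table shipped with the package follows this convention (its
printed lengths equal the coordinate differences exactly). A gene or TE is
counted if its span overlaps the interval at all; containment counting is
available via `overlap="within"`. Candidate selection drops any region
containing a lethal-flagged gene. Gene redundancy categories are assigned
with priority syntenic_paralogue > multigene_orthogroup > single_copy: a
block anchor is always a syntenic paralogue even when its orthogroup is
large, and genes missing from the orthogroup table are treated as
singletons. The homeologous interval of a deletion is the minimal B-side
interval spanning the partners of all anchors whose A-side gene overlaps
the deletion.

## Off-target search

The search reimplements Cas-OFFinder semantics for 21-nt spacers: both
strands are scanned for PAM motifs (default NNGRRT, the canonical SaCas9
PAM — the nuclease's PAM must be overridden when it differs), and at each
PAM every protospacer length between 21 − `max_rna_bulge` and
21 + `max_dna_bulge` is aligned with exactly one contiguous bulge (extra
genomic bases = DNA bulge; extra spacer bases = RNA bulge) plus bounded
substitutions (defaults: 3 mismatches, DNA bulge ≤ 2, RNA bulge ≤ 1). PAM
bases are outside the mismatch budget. Genomic N never matches. One hit is
reported per (chromosome, strand, PAM position), choosing the alignment
minimizing (bulge size, mismatches) lexicographically; overlapping hits at
different PAM positions are reported separately. `search_bruteforce`
re-derives the same hit set by enumerating every position, strand, length
and gap placement with no indexing or regular expressions; the two must
agree exactly, and the test suite enforces this on genomes up to 50 kb.

## Counts and differential expression

`generate_counts` draws negative-binomial counts (gamma–Poisson, variance
μ + αμ² with α = `nb_dispersion`, default 0.05) around per-gene lognormal
baselines (median 100). Genes inside the deletion have their mean scaled by
copy number: 1.0 in wild type, 0.5 in heterozygotes, 0 in homozygotes —
the linear dosage model. When `compensation_effect` = c ≠ 0, retained
same-orthogroup paralogues of deleted genes have their means multiplied by
2^c in the deletion genotypes only.

Normalization is median-of-ratios: factor_j is the median over
all-positive genes of count_gj ÷ geometric-mean_g. Differential expression
is a per-gene NB log-linear model with a two-level genotype design fitted
by IRLS (statsmodels GLM). The gene-wise dispersion maximizes the Cox-Reid
adjusted profile likelihood (the profile likelihood penalized by half the
log-determinant of the weighted information, the GLM analogue of REML),
floored at 1e-8. Plain per-gene ML dispersion is biased low with 6
replicates per group and makes the Wald test reject ~10% at nominal 5%;
the CR adjustment with a t reference at residual degrees of freedom brings
the null rejection rate to ~4.5–5%, which the calibration tests enforce.
No empirical-Bayes shrinkage of dispersions or fold changes is applied —
the model is deliberately transparent and validated by calibration and
effect-recovery tests rather than by identity with any specific package.
DE status uses FDR < 0.05 (Benjamini-Hochberg across genes) with no
fold-change floor; both thresholds are configurable. Two-timepoint designs
are analyzed as separate per-timepoint contrasts, not an interaction model.

Orthogroup dosage sums normalized counts of an affected orthogroup's
members inside and outside the deletion per sample, compares group means
between mutant and wild type (sums, not means, per the group-total
definition), and tests the out-of-region totals with a two-sided Welch
t-test (the distributional comparison is not tied to a named test upstream;
Welch is the documented default and is swappable).

## Network analyses

The coexpression network is an input (a weighted undirected gene graph with
a module partition), never inferred here. Centrality is weighted network
connectivity (WNC): the sum of a gene's incident edge weights. The
centrality of a deleted gene set is its mean WNC compared with a null of
10,000 bootstrap draws of equal-size gene sets sampled without replacement
from all genes (deleted genes are not excluded from the sampling universe);
the two-tailed p-value is the fraction of draws deviating from the
bootstrap mean at least as much as the observed mean. Module enrichment is
an upper-tail hypergeometric test per module, BH-corrected across the
module family, reporting log2(observed/expected) with a 0.5 pseudo-count on
zero overlaps (depletion is available as an option). Connectivity-to-DE
regression takes, for every non-deleted gene, the strongest edge weight to
any deleted gene and fits a logistic model of binary DE status on that
weight; reported are the ML slope, Wald p-value, and McFadden pseudo-R²
(1 − llf/llnull, clipped to [0, 1)); BH correction is applied jointly
across all rows of one invocation. Complete separation and zero-variance
designs are flagged instead of reporting a diverged coefficient.
`exclude_and_rerun` removes every edge of one deleted gene, recomputes the
connectivity and refits — the diagnostic for a single hub driving the
association. Density filtering for visualization keeps the
round(target × n) heaviest edges (default 2.15 per gene) and drops genes
left isolated.

## Numerical and design notes

- Wald rather than likelihood-ratio p-values throughout, matching common
  GLM practice; the logistic fit is verified against a generic numerical
  MLE to 1e-6 in log-likelihood.
- Bootstrap draws use the k-smallest-of-random-keys construction, which is
  an exact uniform without-replacement sample and vectorizes; a relative
  1e-12 epsilon in the tail comparison guards the degenerate case where
  the gene set is the whole universe.
- The uniformity of bootstrap p-values is checked with a
  Kolmogorov–Smirnov statistic over 1,000 random gene sets of 20 genes at
  500 draws each; with this sample count the expected KS statistic under
  exact uniformity (≈0.87/√n ≈ 0.027) sits well below the 0.05 bound the
  check uses, so the bound is discriminating rather than noise-dominated.
- Calibration and recovery suites run at reduced scale (two chromosomes of
  1,000 genes, 2,000 genes for DE calibration, 50 kb off-target genomes),
  sizes at which the Monte-Carlo error of each checked quantity is several
  times smaller than its acceptance band.
- Dosage-ratio checks use deletions spanning ~5% of simulated genes. Real
  deletions are far smaller relative to a genome (tens of genes out of
  ~27,000); a simulated deletion spanning a large fraction of a small
  synthetic genome visibly biases median-of-ratios normalization, which is
  a property of normalization under massive differential signal, not of
  the dosage statistic.

## Known limitations

- The NB model has no dispersion-trend or shrinkage moderation, so power
  at very low counts is below that of moderated pipelines.
- Chaining score ignores gap lengths, so among equal-count chains a gappy
  chain can tie a compact one (ties are broken positionally).
- The off-target search allows one bulge per alignment; sites explainable
  only by mixed DNA+RNA bulges are not reported (matching the reference
  semantics).
- Block counting reports one record per block pair; whether published
  block totals count pairs once or twice is not recoverable, so no
  assertion is made against any published block count.
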