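# Methods

This note documents the models and procedures implemented in `cccdiff`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Communication strength model

For every (sender cell type, receiver cell type, L-R interaction) triple
the pipeline computes a mass-action interaction strength from cell-type
summary expression.

**Cell-type summary.** The default summary is the 25%-truncated mean
(trimean) of expression across the cells of a type: sort the cells'
values, drop the lowest and highest quartiles, average the middle half.
An arithmetic mean is available via `summary="mean"`. A geometric mean
*across cells* is deliberately not offered: on zero-inflated single-cell
data it nulls almost every gene, and in this model family the geometric
mean belongs at the complex level (below). The truncated mean is robust to
outlier cells and, together with the expression-fraction filter, behaves
sensibly on sparse data.

**Expression-fraction filter.** Any (cell type, gene) in which the gene is
expressed (> 0) in less than 20% of the type's cells has its summary
forced to zero (`threshold=0.2`, configurable; exactly 20% is kept). The
filter is recomputed inside every permutation so that observed and
permuted strengths face the same rule.

**Complexes.** A ligand or receptor may be a heteromeric complex; its
expression is the geometric mean of the subunit summaries and is zero if
any subunit is zero or absent from the matrix (absent genes are reported
once, as a warning, not an error).

**Strength.** With ligand summary L, receptor summary R and
half-saturation constant Kh (default 0.5, the convention of mass-action
CCC scoring; configurable via `HillParams.kh`):

    R' = R * (1 + CS/(Kh+CS)) * Kh/(Kh+CI)
    P  = (L*R')/(Kh + L*R') * (1 + AG/(Kh+AG)) * Kh/(Kh+AN)

CS/CI are the receiver's co-stimulatory/co-inhibitory co-receptor
summaries and AG/AN the sender's soluble agonist/antagonist summaries,
each the arithmetic mean over the respective cofactor gene set (an empty
set contributes no modulation). Cofactors are stored as flat gene lists,
not complexes, and can be disabled (`use_cofactors=False`; they default to
on). P is monotone non-decreasing in L, R, AG, CS and non-increasing in
AN, CI; without cofactors P ∈ [0, 1), with cofactors P < 2.

**Significance.** Cell-type labels are shuffled — globally by default, or
within each sample in the per-sample design (`perm_within="sample"`),
keeping per-type cell counts fixed — and the full pipeline (summary,
filter, strength) is recomputed. The p-value is the add-one estimator
p = (1 + #{permuted ≥ observed}) / (1 + n_perm) with an inclusive ≥, so p
is never zero and ties count against significance (conservative). A triple
with observed strength zero is assigned p = 1 by convention. Defaults:
n_perm = 100, alpha = 0.05.

## Aggregation

Pathway scores sum the *significant* strengths of a pathway's interactions
per (sender, receiver) pair; each interaction belongs to exactly one
pathway, so pathways partition the database and the total information flow
(pathway score summed over all cell pairs, then over pathways) equals the
total significant strength exactly — a conservation law the tests assert.
Relative information flow normalizes two conditions' flows per pathway to
shares summing to 1; pathways with flow in exactly one condition are
labeled condition-specific, and pathways silent in both are dropped with a
log entry. Outgoing/incoming contributions sum scores over receivers or
senders respectively; the relative form scales each pathway column to a
maximum of 1.

## Differential designs

**Global.** Cells of each condition are merged, inference runs once per
condition (both runs share the permutation seed, so identical inputs give
identical significance masks and a self-comparison is exactly zero), and
the conditions are contrasted by per-cell-pair significant-interaction
counts and total strengths, plus a per-pathway two-sided Wilcoxon
signed-rank test pairing the two conditions' cell-pair score vectors
(zeros included, `zsplit` zero handling; an all-zero difference vector
gives p = 1). This test sees pathway-wide shifts across many cell pairs;
a signal confined to a single cell pair among hundreds cannot move it —
which is exactly why the per-sample design exists.

**Per-sample (pseudo-bulk).** Inference runs independently inside every
sample (per-sample permutation seeds derived from one master seed); a
sample with fewer than two populated cell types contributes a zero row and
is flagged. A pathway is "detected" in a sample when its score is positive
after significance filtering. Pathways detected in fewer than
`min_samples = 5` samples (both groups pooled) are removed; detection in
exactly 5 retains the pathway. Per-pathway and per-(cell pair, L-R) sample
scores are then compared between groups with a two-sided Wilcoxon rank-sum
test — exact null distribution when both groups have ≤ 10 tie-free
observations, normal approximation with tie correction otherwise — and
BH-corrected within each family. Fold changes use
(mean_A + ε)/(mean_B + ε) with ε = 10⁻³ × the smallest positive observed
score (logged), so zero group means stay finite. A unit constant across
all samples is flagged degenerate with p = 1. Alternative groupings (for
example a balanced 4-vs-4 regrouping) are configurations of the same code
path via an explicit sample-to-group map.

**PCA** of the sample × pathway matrix is centered but not scaled:
pathway scores share units, and scaling would inflate noise-dominated
pathways. Variance fractions sum to 1.

**Subsampling robustness** repeats the global comparison on random cell
subsets (default 50%, 10 repetitions) and reports the element-wise mean/SD
of the strength-difference maps and each repetition's Pearson correlation
with the full-data differences. `frac=1.0` reproduces the full-data result
exactly (same seed path), which the tests use as an identity check.

## Communication patterns (NMF)

The cell-type × pathway signaling matrix (outgoing or incoming; pathway
columns scaled to max 1, undetected pathways dropped) is factored as
M ≈ WH by multiplicative-update NMF under Frobenius loss, initialized from
seeded uniform (0, 1] draws scaled by the matrix mean; the reconstruction
error is non-increasing by construction and a non-converged fit (500
iterations, relative tolerance 10⁻⁶) is returned with a warning flag, not
an error. Rows of W are normalized to sum to 1 (a silent cell type gets a
uniform loading).

The number of patterns k is chosen by consensus clustering: for each
candidate k (default 2…10, bounded by the matrix), 30 NMF runs assign each
cell type to its argmax pattern; the co-assignment frequencies form a
consensus matrix whose cophenetic correlation (average-linkage dendrogram
vs consensus distances) and mean silhouette (on consensus distances, with
the dendrogram's k-cluster cut) measure stability. The selection rule —
the largest k at which both metrics hold ≥ 95% of their k = 2 value,
falling back to the argmax of the cophenetic coefficient — is this
package's choice; the literature names the metrics but not a rule, so both
diagnostics are always emitted and k can be overridden. All loadings are
reported; no "minor contributor" cutoff is applied.

## Enrichment statistics

ORA: p = P(X ≥ k) under Hypergeometric(N, K, n) with BH across sets; the
default universe is the measured gene list (configurable), and set members
outside the universe are intersected away with a log entry. Overlap test:
2×2 Fisher exact (two-sided) with the sample odds ratio (a·d)/(b·c),
Haldane-corrected by 0.5 when a cell is zero. Preranked GSEA: weighted
(weight 1) KS running-sum ES on the fold-change-ranked gene list; the null
permutes gene labels (equivalent to random same-size sets), matching the
preranked setting — phenotype permutation would require per-sample
expression, which a preranked list no longer has. NES divides ES by the
mean |null ES| of the same sign; FDR follows the pooled positive/negative
null procedure; default FDR cutoff 25%, minimum set size 5 (configurable
down to 1). A set covering the whole ranking has no miss steps; its ES is
defined as the deviation of the weighted hit accumulation from the uniform
walk, which is small — the degenerate case behaves continuously. GO
hierarchies and term-redundancy clustering are out of scope; sets are
supplied flat (GMT).

## Spatial co-expression

L-R pairs are reduced to per-gene (ligand subunit × receptor subunit)
pairs, flagged when complex-derived, since spot-level complex
summarization is not obviously meaningful. Pearson r is computed over all
spots or within one layer (layers with < 10 spots are skipped with a
warning); a constant gene yields a flagged missing value. The null draws
uniform non-interacting gene pairs (≥ 100; with replacement only when the
pool is too small, logged). The true-vs-null comparison reports the
two-sample KS statistic and p — a quantification chosen here in place of
visual density comparison — plus a one-sided Mann-Whitney p for
stochastic dominance.

## Synthetic data generator

The generator emulates the target study design: 17 cortical cell-type
labels, 13 case vs 10 control samples, ~50 cells per type per sample
(uniform in 35–65), two conditions. Counts are negative binomial
(dispersion size 10) around per-gene log-normal baseline means (log-mean
0, log-SD 0.5), multiplied by log-normal per-sample-per-gene effects with
SD 0.25 — noise that survives library normalization and makes pseudo-bulk
tests genuinely variable — then library-normalized to the median cell
total and log2(1+x)-transformed. Counts-first simulation makes zeros, and
hence the 20% filter, realistic.

Ligand/receptor genes are cell-type-specific, as in cortical tissue:
outside their planted routes, database genes sit at 3% of baseline —
essentially silent and safely below the 20% filter even for genes with a
high baseline mean. (An earlier 10% off-state let high-baseline genes
flicker across the filter from sample to sample, which swamped pathway
scores with on/off noise; real off-state ligands do not do this.) A
planted signal (pathway, sender, receiver, fold_change, condition) turns
the pathway's ligands on in the sender and receptors in the receiver in
both conditions, and multiplies the sender's ligand means by fold_change
in the designated condition; fold_change = 1 plants an active-but-null
route, which is how null calibration scenarios keep scores continuous.
The truth table lists every planted route.

What the generator does **not** emulate: batch or chemistry effects,
doublets, dropout beyond NB zeros, gene-gene correlation beyond the
planted structure, or cell-type-specific library sizes. Passing tests
therefore show the statistics behave correctly under the stated model,
not that the pipeline is robust to every artifact of real tissue data.

The spatial generator assigns spots to six layers plus white matter
uniformly at random and draws planted pairs from a bivariate normal on
the expression scale (mean 2, SD 0.5, clipped at 0; clipping is
negligible at these parameters), so realized Pearson r tracks the target
ρ closely; background genes are independent.

## Benchmark problem sizes

The evaluation scenarios (`cccdiff.evaluation`, run by
`scripts/acceptance.py` and the acceptance tests) use: 200 random
instances for the rank-sum enumeration oracle and universes ≤ 12 for the
hypergeometric one; 10 independent single-sample datasets × 50 triples
for permutation-p uniformity (independent datasets keep the shared-
permutation dependence from distorting the KS test); 20 replicates × 50
null pathways (13 vs 10 samples) for the pseudo-bulk type-I error; 100
replicates of a 4-type, 4-pathway design at ~100 cells/type/sample for
detection power, and 20 seeds of the full 30-pathway, 17-type reference
study for end-to-end recovery; 20 seeds of 10×12 two-block matrices for
NMF recovery; and 50 planted ρ = 0.5 pairs vs 400 random pairs at 200
spots for spatial dominance. These sizes keep the whole benchmark under a
few minutes on one CPU while leaving each metric well-determined.

## Known limitations

- Strength saturates for well-expressed genes (L·R ≫ Kh), compressing
  fold changes at the score level; the pseudo-bulk test still detects
  planted 2× ligand shifts with power ≈ 0.9+ at 13 vs 10 samples, but
  effect-size estimates understate expression-level changes.
- The global paired pathway test is insensitive to signals confined to
  very few cell pairs (see above); use the per-sample design for
  localized effects.
- Permutation p-values are granular at 1/(n_perm+1); with the default 100
  permutations the smallest attainable p is ≈ 0.0099.
- Library normalization couples genes: a strong planted perturbation in a
  small gene universe shifts other genes' normalized values
  (composition artifact). With realistic universe sizes (≥ 150 genes) the
  effect is negligible; the type-I benchmarks run in that regime.
- The rank-sum normal approximation is used for groups larger than 10;
  at 13 vs 10 its size is within the tested [0.03, 0.075] band but not
  exact.
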