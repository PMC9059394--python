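# cccdiff

Differential cell–cell communication (CCC) analysis between two groups of
annotated single-nucleus RNA-seq samples — for example autism-spectrum vs
control cortex — built for transcriptomics researchers who want the whole
chain from ligand–receptor (L-R) scoring to group-level statistics in one
tested, scriptable package.

Given a UMI-normalized, log-transformed genes × cells matrix with cell-type,
sample and condition labels, plus an L-R interaction database with
heteromeric complexes, cofactors and pathway families, the pipeline:

1. scores every (sender cell type, receiver cell type, interaction) triple
   with a mass-action model and tests it by cell-type label permutation;
2. aggregates significant strengths into pathway scores, "information
   flow" and per-cell-type outgoing/incoming contributions;
3. contrasts the two sample groups through a merged **global** design and a
   per-sample **pseudo-bulk** design (Wilcoxon tests, BH FDR, PCA,
   subsampling robustness);
4. extracts latent outgoing/incoming communication patterns by consensus
   NMF;
5. provides downstream gene-set statistics (hypergeometric ORA, Fisher
   overlap, preranked GSEA) and spatial L-R co-expression checks;
6. ships a synthetic-data generator with planted ground truth so every
   stage is testable without external downloads.

## The model

Per cell type, gene expression is summarized by a 25%-truncated mean over
cells (trimean); genes expressed in < 20% of a type's cells are zeroed.
Complex expression is the geometric mean over subunits, so one missing
subunit nulls the interaction. With ligand summary *L*, receptor summary
*R* and half-saturation constant *K<sub>h</sub>* (default 0.5), the
communication strength of a triple is the Hill-type response

```
P = (L·R′) / (Kh + L·R′) · (1 + AG/(Kh+AG)) · Kh/(Kh+AN)
R′ = R · (1 + CS/(Kh+CS)) · Kh/(Kh+CI)
```

where AG/AN are sender-side agonist/antagonist summaries and CS/CI
receiver-side co-stimulatory/co-inhibitory co-receptor summaries. Without
cofactors P lies in [0, 1). Significance comes from shuffling cell-type
labels (globally or within samples), recomputing the full pipeline, and
the add-one estimator p = (1 + #{permuted ≥ observed}) / (1 + n_perm).
Pathway scores are the sums of *significant* strengths over each pathway's
interactions; summing over all cell pairs gives the pathway's information
flow.

In the pseudo-bulk design, inference runs separately inside each sample,
pathways detected in fewer than 5 samples are removed, and per-pathway /
per-L-R sample scores are compared between groups with two-sided Wilcoxon
rank-sum tests (exact for small tie-free groups) and BH correction per
family.

## Worked example

Simulate a 13-vs-10-sample study with one differential pathway (its
ligands doubled in the case group, route A→B) among four active pathways,
then run the pseudo-bulk design:

```python
from cccdiff import (HillParams, PlantedSignal, SimConfig, filter_pathways,
                     generate_dataset, generate_toy_db, per_sample_scores,
                     sample_wilcoxon)

db = generate_toy_db(n_pathways=4, interactions_per_pathway=3, seed=2)
signals = [PlantedSignal("PW00", "A", "B", fold_change=2.0, condition="case"),
           PlantedSignal("PW01", "B", "C", fold_change=1.0),
           PlantedSignal("PW02", "C", "D", fold_change=1.0),
           PlantedSignal("PW03", "D", "A", fold_change=1.0)]
cfg = SimConfig(n_genes=150, cell_types=("A", "B", "C", "D"),
                n_case=13, n_control=10, cells_per_sample_per_type=(80, 120),
                db=db, planted_signals=signals, seed=42)
ds, truth = generate_dataset(cfg)

sls = per_sample_scores(ds, db, HillParams(n_perm=100), seed=1)
table = sample_wilcoxon(filter_pathways(sls))["pathways"]
print(table[["unit", "mean_case", "mean_control", "fold_change", "p", "fdr"]]
      .round(4).to_string(index=False))
```

prints

```
unit  mean_case  mean_control  fold_change      p    fdr
PW00     2.0643        1.6684       1.2372 0.0011 0.0045
PW01     0.7832        0.8027       0.9757 1.0000 1.0000
PW02     1.5333        1.5756       0.9732 0.5981 0.7975
PW03     1.5408        1.6055       0.9597 0.5558 0.7975
```

The planted pathway PW00 is the only one called (p = 0.0011, FDR 0.0045);
its pseudo-bulk score rises 1.24-fold — less than the planted ligand
fold-change of 2 because the Hill response saturates — while the three
null pathways sit at p ≥ 0.55. `truth` records the planted route for
comparison.

## Analysis scripts

`analysis/01_simulate.py` … `07_spatial.py` run a complete reference study
(30 pathways, 5 differential, 17 cortical cell types, 13 vs 10 samples)
and write tables under `results/`: ground truth and design balance, global
count/strength difference maps and relative information flow, NMF
patterns per condition, pseudo-bulk differential pathways and L-R units
with PCA, 50%-subsampling robustness, ORA/overlap/GSEA, and spatial
co-expression. Each script prints a short summary of what it found; on
this reference study the pseudo-bulk design recovers all 5 planted
pathways with no false positives, while the global paired test cannot
resolve single-cell-pair signals — the motivation for running both
designs.

A command-line interface wraps the same pipeline for on-disk data:

```bash
cccdiff simulate --config sim.yaml --out data/ --seed 3
cccdiff run --matrix data/matrix.mtx --genes data/genes.tsv \
            --meta data/metadata.tsv --lrdb data/lr_database.tsv \
            --mode per-sample --out results/ --seed 4
```

The L-R database TSV schema (and how to export CellChatDB or CellPhoneDB
into it) is documented in `docs/lr_database_format.md`; the modeling
choices and their rationale are in `docs/methods.md`.

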