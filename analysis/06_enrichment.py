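"""Downstream gene-set statistics for the dysregulated pathways.

Takes the genes of the pathways called differential by the pseudo-bulk
design, tests them for overrepresentation against synthetic GO-style sets
(one of which is enriched for planted-pathway genes by construction),
tests overlap with a synthetic disorder gene list, and runs preranked GSEA
on a fold-change ranking.  Tables go to results/enrichment/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, params, reference_study

from cccdiff import (
    GeneSetCollection,
    filter_pathways,
    ora,
    overlap_test,
    pathway_gene_set,
    per_sample_scores,
    preranked_gsea,
    sample_wilcoxon,
)

ds, db, truth = reference_study()
out = RESULTS / "enrichment"
out.mkdir(parents=True, exist_ok=True)
rng = np.random.default_rng(SEED)

sls = filter_pathways(per_sample_scores(ds, db, params(), seed=SEED + 2))
tab = sample_wilcoxon(sls)["pathways"].set_index("unit")
dysregulated = sorted(tab.loc[tab.p < 0.05].index)
query = sorted({g for pw in dysregulated for g in pathway_gene_set(db, pw)})

# synthetic GO-style sets over the measured gene universe: one set built
# around planted-pathway genes, the rest random
universe = list(ds.genes)
planted_genes = {g for pw in truth.loc[truth.differential, "pathway"]
                 for g in pathway_gene_set(db, pw)}
sets = {"planted_module": sorted(planted_genes)
        + list(rng.choice([g for g in universe if g not in planted_genes],
                          10, replace=False))}
for i in range(5):
    sets[f"random_set_{i}"] = list(rng.choice(universe, 40, replace=False))
collection = GeneSetCollection(sets, universe)

ora_tab = ora(query, collection)
ora_tab.to_csv(out / "ora.tsv", sep="\t", index=False)

# synthetic disorder list sharing half of the planted genes
disorder = sorted(rng.choice(sorted(planted_genes),
                             len(planted_genes) // 2, replace=False))
disorder += list(rng.choice([g for g in universe if g not in planted_genes],
                            30, replace=False))
ov = overlap_test(query, disorder, universe)
pd.DataFrame([ov]).to_csv(out / "overlaps.tsv", sep="\t", index=False)

# preranked GSEA on a pseudo-bulk fold-change ranking for one cell type
sender = truth.iloc[0]["sender"]
mask = ds.cell_type == sender
cond = ds.condition_of_cells()
mean_case = ds.matrix[:, mask & (cond == "case")].mean(axis=1)
mean_ctrl = ds.matrix[:, mask & (cond == "control")].mean(axis=1)
ranking = pd.Series(np.log2((mean_case + 0.01) / (mean_ctrl + 0.01)),
                    index=ds.genes)
gsea = preranked_gsea(ranking, collection.sets, n_perm=500, seed=SEED)
gsea.to_csv(out / f"gsea_{sender.replace('/', '-')}.tsv", sep="\t", index=False)

print(f"dysregulated pathways: {dysregulated}")
print(f"query genes: {len(query)}")
print(ora_tab[["set", "overlap", "p", "q", "significant"]].to_string(index=False))
print(f"disorder-list overlap: OR = {ov['odds_ratio']:.2f}, p = {ov['p']:.3g}")
print(gsea[["set", "es", "nes", "p", "fdr"]].to_string(index=False))
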