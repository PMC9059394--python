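"""Global (merged two-group) communication comparison.

Merges all case cells into one group and all control cells into another,
infers the communication tensor per group, and writes the per-cell-pair
count/strength difference maps, per-pathway information flow with relative
flow, and the paired pathway tests to results/global/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, params, reference_study

from cccdiff import global_compare, relative_flow

ds, db, truth = reference_study()
out = RESULTS / "global"
out.mkdir(parents=True, exist_ok=True)

cmp = global_compare(ds, db, params(), seed=SEED + 1)
cmp.count_diff.to_csv(out / "count_diff.tsv", sep="\t")
cmp.strength_diff.to_csv(out / "strength_diff.tsv", sep="\t")
cmp.pathway_tests.to_csv(out / "differential_pathways.tsv", sep="\t", index=False)
rel = relative_flow(cmp.scores_a, cmp.scores_b)
rel.to_csv(out / "relative_information_flow.tsv", sep="\t")

n_sig_a = int(cmp.tensor_a.significant.sum())
n_sig_b = int(cmp.tensor_b.significant.sum())
print(f"significant interactions: case {n_sig_a}, control {n_sig_b}")
print(f"cell pairs with increased strength in case: "
      f"{(cmp.strength_diff.to_numpy() > 0).sum()}, decreased: "
      f"{(cmp.strength_diff.to_numpy() < 0).sum()}")
planted = set(truth.loc[truth.differential, 'pathway'])
flagged = set(cmp.pathway_tests.loc[cmp.pathway_tests.p < 0.05, 'pathway'])
print(f"pathways flagged by paired test: {sorted(flagged)} "
      f"(planted: {sorted(planted)})")
if not flagged & planted:
    print("note: each planted pathway signals through a single cell pair, "
          "which the paired test over all 289 cell pairs cannot resolve — "
          "the per-sample design (04) is the sensitive one for localized "
          "signals")
print(f"condition-specific pathways: "
      f"{rel.loc[rel.label != 'shared'].index.tolist()}")
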