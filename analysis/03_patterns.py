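"""Latent outgoing/incoming communication patterns per condition.

For each condition's pathway scores, builds the cell-type x pathway
signaling matrix, selects the number of NMF patterns from consensus
cophenetic/silhouette diagnostics, and writes cell and pathway loadings to
results/patterns/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, params, reference_study

from cccdiff import global_compare
from cccdiff.patterns import build_signaling_matrix, detect_patterns, select_k

ds, db, _ = reference_study()
out = RESULTS / "patterns"
out.mkdir(parents=True, exist_ok=True)

cmp = global_compare(ds, db, params(), seed=SEED + 1)
for label, scores in ((cmp.condition_a, cmp.scores_a),
                      (cmp.condition_b, cmp.scores_b)):
    for direction in ("outgoing", "incoming"):
        M = build_signaling_matrix(scores, direction)
        k, diag = select_k(M, k_range=range(2, 8), runs_per_k=30, seed=SEED)
        pat = detect_patterns(M, k, seed=SEED, direction=direction,
                              diagnostics=diag)
        stem = f"{direction}_{label}"
        pat.cell_loadings.to_csv(out / f"patterns_{stem}.tsv", sep="\t")
        pat.pathway_loadings.to_csv(out / f"pattern_pathways_{stem}.tsv", sep="\t")
        diag.to_csv(out / f"pattern_diagnostics_{stem}.tsv", sep="\t", index=False)
        tops = pat.top_members(3)
        print(f"{label} {direction}: k = {k}")
        for _, row in tops.iterrows():
            print(f"  {row['pattern']}: cells [{row['top_cell_types']}] "
                  f"pathways [{row['top_pathways']}]")
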