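"""Shared configuration for the analysis scripts.

One reference synthetic study: 30 pathways (3 L-R interactions each), 5 of
them planted as differential (ligand fold-change 2 in the case group), 17
cortical cell types, 13 case vs 10 control samples, ~50 cells per type per
sample.  All scripts derive their data from this configuration and a fixed
seed so every table under results/ is reproducible.
"""

from pathlib import Path

from cccdiff import HillParams, default_study_config, generate_dataset, generate_toy_db

SEED = 20230917
RESULTS = Path(__file__).resolve().parent.parent / "results"


def reference_study(seed: int = SEED):
    """Dataset, database and truth table of the reference study."""
    db = generate_toy_db(n_pathways=30, interactions_per_pathway=3, seed=7)
    cfg = default_study_config(seed=seed, db=db)
    ds, truth = generate_dataset(cfg)
    return ds, db, truth


def params() -> HillParams:
    return HillParams(kh=0.5, use_cofactors=True, n_perm=100, alpha=0.05)
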