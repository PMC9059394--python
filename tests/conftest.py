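"""Shared fixtures: tiny databases and datasets built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from cccdiff import (
    ExpressionDataset,
    GeneComplex,
    LRDatabase,
    LRInteraction,
    PlantedSignal,
    SimConfig,
    generate_dataset,
    generate_toy_db,
)


@pytest.fixture
def tiny_db() -> LRDatabase:
    """Two pathways, three interactions, one receptor complex, cofactors."""
    return LRDatabase(
        interactions=[
            LRInteraction(
                id="I1",
                ligand=GeneComplex("FGF1", ("FGF1",)),
                receptor=GeneComplex("FGFR1", ("FGFR1",)),
                pathway="FGF",
            ),
            LRInteraction(
                id="I2",
                ligand=GeneComplex("FGF2", ("FGF2",)),
                receptor=GeneComplex("FGFR1_FGFR2", ("FGFR1", "FGFR2")),
                pathway="FGF",
                agonists=("AGO1",),
            ),
            LRInteraction(
                id="I3",
                ligand=GeneComplex("NRXN1", ("NRXN1",)),
                receptor=GeneComplex("NLGN1", ("NLGN1",)),
                pathway="NRXN",
                antagonists=("ANT1",),
            ),
        ]
    )


def make_dataset(values: dict[str, dict[str, float]], n_cells: int = 10,
                 n_samples: int = 2) -> ExpressionDataset:
    """Constant-valued dataset: values[cell_type][gene] -> every cell.

    Constant expression makes every summary statistic exact, so strength
    oracles can be computed by hand.
    """
    cell_types = sorted(values)
    genes = sorted({g for v in values.values() for g in v})
    cells, ct_labels, smp_labels, cols = [], [], [], []
    for ct in cell_types:
        for i in range(n_cells):
            cells.append(f"{ct}_{i}")
            ct_labels.append(ct)
            smp_labels.append(f"s{i % n_samples + 1}")
            cols.append([values[ct].get(g, 0.0) for g in genes])
    matrix = np.array(cols).T
    condition = {f"s{j + 1}": ("case" if j % 2 == 0 else "control")
                 for j in range(n_samples)}
    return ExpressionDataset(
        matrix=matrix,
        genes=genes,
        cells=cells,
        cell_type=np.array(ct_labels, object),
        sample=np.array(smp_labels, object),
        condition=condition,
    )


@pytest.fixture
def planted_small():
    """Small planted-signal dataset: 4 types, 4 pathways, 1 differential."""
    db = generate_toy_db(4, 2, seed=2)
    types = ("A", "B", "C", "D")
    sigs = [
        PlantedSignal("PW00", "A", "B", 2.0, "case"),
        PlantedSignal("PW01", "B", "C", 1.0, "case"),
        PlantedSignal("PW02", "C", "D", 1.0, "case"),
        PlantedSignal("PW03", "D", "A", 1.0, "case"),
    ]
    cfg = SimConfig(
        n_genes=60,
        cell_types=types,
        n_case=3,
        n_control=3,
        cells_per_sample_per_type=(25, 35),
        db=db,
        planted_signals=sigs,
        seed=11,
    )
    ds, truth = generate_dataset(cfg)
    return ds, db, truth
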