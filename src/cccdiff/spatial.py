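"""Spatial co-expression of ligand-receptor pairs.

Given spot-level spatial expression with cortical-layer labels, curated
L-R pairs are tested for being more co-expressed across spots than random
gene pairs: per-pair Pearson correlations are compared with a null of
uniformly drawn non-interacting gene pairs via two-sample statistics,
either over all spots or restricted to one layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lr_resource import LRDatabase

logger = logging.getLogger(__name__)

MIN_LAYER_SPOTS = 10


@dataclass
class SpatialDataset:
    """Genes x spots normalized expression with per-spot layer labels."""

    matrix: np.ndarray
    genes: list[str]
    layer: np.ndarray  # per-spot label; "NA" allowed

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.layer = np.asarray(self.layer, dtype=object)
        if self.matrix.shape[0] != len(self.genes):
            raise ValueError("matrix rows must match gene list")
        if self.matrix.shape[1] != len(self.layer):
            raise ValueError("every spot needs a layer label")
        if np.any(self.matrix < 0):
            raise ValueError("expression values must be non-negative")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def layers(self) -> list[str]:
        return sorted(set(self.layer))

    def gene_row(self, gene: str) -> np.ndarray:
        return self.matrix[self._index[gene]]


def db_gene_pairs(db: LRDatabase) -> pd.DataFrame:
    """Flatten a database into per-gene (ligand, receptor) pairs.

    Heteromeric complexes are expanded to every ligand-subunit x
    receptor-subunit combination, flagged ``complex_derived``.
    """
    rows = []
    for it in db.interactions:
        is_complex = len(it.ligand.subunits) > 1 or len(it.receptor.subunits) > 1
        for lg in it.ligand.subunits:
            for rg in it.receptor.subunits:
                rows.append(
                    {"ligand": lg, "receptor": rg, "interaction": it.id,
                     "complex_derived": is_complex}
                )
    return pd.DataFrame(rows)


def _spot_mask(sp: SpatialDataset, layer: str | None) -> np.ndarray:
    if layer is None:
        return np.ones(sp.matrix.shape[1], dtype=bool)
    mask = sp.layer == layer
    if mask.sum() < MIN_LAYER_SPOTS:
        logger.warning("layer %s has %d (< %d) spots; skipped", layer,
                       int(mask.sum()), MIN_LAYER_SPOTS)
        return np.zeros_like(mask)
    return mask


def lr_spatial_correlation(
    sp: SpatialDataset,
    pairs: list[tuple[str, str]] | pd.DataFrame,
    layer: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation per (ligand gene, receptor gene) pair.

    ``layer=None`` uses all spots; otherwise spots of that layer (layers
    with fewer than 10 spots are skipped).  A gene constant across the
    in-scope spots yields an undefined correlation, emitted as missing
    with a flag.
    """
    if isinstance(pairs, pd.DataFrame):
        pair_list = list(zip(pairs["ligand"], pairs["receptor"]))
    else:
        pair_list = list(pairs)
    mask = _spot_mask(sp, layer)
    rows = []
    for lg, rg in pair_list:
        flag = ""
        r = np.nan
        if lg not in sp._index or rg not in sp._index:
            flag = "gene_missing"
        elif mask.sum() < 3:
            flag = "too_few_spots"
        else:
            x = sp.gene_row(lg)[mask]
            y = sp.gene_row(rg)[mask]
            if np.std(x) == 0 or np.std(y) == 0:
                flag = "constant_gene"
            else:
                r = float(stats.pearsonr(x, y).statistic)
        rows.append({"ligand": lg, "receptor": rg, "layer": layer or "all",
                     "r": r, "n_spots": int(mask.sum()), "flag": flag})
    return pd.DataFrame(rows)


def random_pair_null(
    sp: SpatialDataset,
    n_pairs: int,
    seed: int = 0,
    exclude: set[tuple[str, str]] | None = None,
    layer: str | None = None,
) -> np.ndarray:
    """Correlations of uniformly drawn gene pairs (the random-pair null).

    True L-R pairs can be excluded; if the gene pool cannot supply enough
    distinct pairs, sampling falls back to replacement (logged).
    """
    if n_pairs < 100:
        raise ValueError("n_pairs must be >= 100 for a usable null")
    rng = np.random.default_rng(seed)
    exclude = exclude or set()
    mask = _spot_mask(sp, layer)
    n_genes = len(sp.genes)
    max_distinct = n_genes * (n_genes - 1) // 2 - len(exclude)
    replace = max_distinct < n_pairs
    if replace:
        logger.warning("gene pool supports %d distinct pairs < %d requested; "
                       "sampling with replacement", max_distinct, n_pairs)
    out = []
    seen: set[tuple[str, str]] = set()
    attempts = 0
    while len(out) < n_pairs and attempts < 100 * n_pairs:
        attempts += 1
        i, j = rng.choice(n_genes, size=2, replace=False)
        gi, gj = sp.genes[i], sp.genes[j]
        if (gi, gj) in exclude or (gj, gi) in exclude:
            continue
        if not replace and ((gi, gj) in seen or (gj, gi) in seen):
            continue
        seen.add((gi, gj))
        x, y = sp.matrix[i][mask], sp.matrix[j][mask]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out.append(float(stats.pearsonr(x, y).statistic))
    return np.asarray(out)


def coexpression_test(
    true_r: np.ndarray, null_r: np.ndarray
) -> dict[str, float]:
    """Compare true-pair and random-pair correlation distributions.

    Reports the two-sample Kolmogorov-Smirnov statistic and p-value
    (distributional difference) and a one-sided Mann-Whitney p for the
    true pairs being stochastically larger.
    """
    true_r = np.asarray(true_r, float)
    true_r = true_r[~np.isnan(true_r)]
    null_r = np.asarray(null_r, float)
    ks = stats.ks_2samp(true_r, null_r)
    mw = stats.mannwhitneyu(true_r, null_r, alternative="greater")
    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "mannwhitney_p": float(mw.pvalue),
        "n_true": int(true_r.size),
        "n_null": int(null_r.size),
    }
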