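"""Annotated expression matrices: ingest, validation, writers.

Input is a genes x cells matrix of already-normalized expression (the study
design this package targets distributes UMI-normalized, log2-transformed
values) together with per-cell metadata assigning each cell a cell type and
a sample, and each sample one of two conditions.  No normalization is
performed here; a heuristic warning fires if column sums vary wildly, which
usually means raw counts were passed by mistake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy import stats

logger = logging.getLogger(__name__)


class DatasetError(ValueError):
    """Inconsistent expression matrix / metadata."""


@dataclass
class ExpressionDataset:
    """Genes x cells normalized expression with cell and sample annotation.

    Attributes
    ----------
    matrix:
        Dense ``(n_genes, n_cells)`` array of non-negative values on a
        log-normalized scale.
    genes, cells:
        Row and column identifiers.
    cell_type, sample:
        Per-cell labels, aligned with ``cells``.
    condition:
        Mapping sample -> condition label (exactly two levels overall).
    region:
        Optional mapping sample -> region label.
    """

    matrix: np.ndarray
    genes: list[str]
    cells: list[str]
    cell_type: np.ndarray
    sample: np.ndarray
    condition: dict[str, str]
    region: dict[str, str] | None = None
    gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.sample = np.asarray(self.sample, dtype=object)
        n_genes, n_cells = self.matrix.shape
        if len(self.genes) != n_genes or len(self.cells) != n_cells:
            raise DatasetError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(self.cell_type) != n_cells or len(self.sample) != n_cells:
            raise DatasetError("per-cell labels do not match cell count")
        if np.any(self.matrix < 0):
            raise DatasetError("expression values must be non-negative")
        missing = sorted(set(self.sample) - set(self.condition))
        if missing:
            raise DatasetError(f"samples without condition: {missing}")
        self.gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.cell_type))

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.sample))

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition.values()))

    def condition_of_cells(self) -> np.ndarray:
        """Condition label per cell (through the sample map)."""
        return np.array([self.condition[s] for s in self.sample], dtype=object)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        """New dataset restricted to the cells selected by a boolean mask."""
        mask = np.asarray(mask)
        cells = [c for c, m in zip(self.cells, mask) if m]
        kept_samples = set(self.sample[mask])
        return ExpressionDataset(
            matrix=self.matrix[:, mask],
            genes=list(self.genes),
            cells=cells,
            cell_type=self.cell_type[mask],
            sample=self.sample[mask],
            condition={s: c for s, c in self.condition.items() if s in kept_samples},
            region=None
            if self.region is None
            else {s: r for s, r in self.region.items() if s in kept_samples},
        )

    def subset_condition(self, level: str) -> "ExpressionDataset":
        return self.subset_cells(self.condition_of_cells() == level)

    def subset_sample(self, sample: str) -> "ExpressionDataset":
        return self.subset_cells(self.sample == sample)


def _read_matrix(matrix_path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Read MTX (genes x cells; gene names supplied separately) or dense TSV
    (first column = gene symbol, header = cell ids)."""
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        return np.asarray(mat, dtype=float), None
    table = pd.read_csv(matrix_path, sep="\t", index_col=0)
    return table.to_numpy(dtype=float), list(table.index)


def load_dataset(
    matrix_path,
    metadata_path,
    genes_path=None,
    region_column: str = "region",
) -> ExpressionDataset:
    """Load an annotated expression dataset from disk.

    Parameters
    ----------
    matrix_path:
        Matrix Market (``.mtx``, genes x cells, requires ``genes_path``) or a
        dense TSV with gene symbols in the first column and cell ids as
        header.
    metadata_path:
        TSV keyed by cell id with ``cell_type``, ``sample`` and ``condition``
        columns (optionally a region column); row order defines cell order
        for MTX input.
    genes_path:
        One gene symbol per line, aligned with MTX rows.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"cell", "cell_type", "sample", "condition"}
    if not required.issubset(meta.columns):
        raise DatasetError(f"metadata needs columns {sorted(required)}")

    matrix, genes = _read_matrix(Path(matrix_path))
    if genes is None:
        if genes_path is None:
            raise DatasetError("MTX input requires a genes file")
        genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        cells = list(meta["cell"])
    else:
        cells = list(pd.read_csv(matrix_path, sep="\t", index_col=0, nrows=0).columns)

    meta = meta.set_index("cell")
    missing = [c for c in cells if c not in meta.index]
    if missing:
        raise DatasetError(f"cells missing from metadata: {missing[:5]}")
    meta = meta.loc[cells]

    cond_per_sample = meta.groupby("sample")["condition"].nunique()
    bad = cond_per_sample[cond_per_sample > 1]
    if len(bad):
        raise DatasetError(f"sample(s) mapped to multiple conditions: {list(bad.index)}")
    condition = meta.groupby("sample")["condition"].first().to_dict()
    region = None
    if region_column in meta.columns:
        region = meta.groupby("sample")[region_column].first().to_dict()

    colsums = matrix.sum(axis=0)
    positive = colsums[colsums > 0]
    if len(positive) and positive.max() > 100 * positive.min():
        logger.warning(
            "per-cell totals vary by more than 100x; input may be raw counts "
            "(this package expects normalized values)"
        )

    ds = ExpressionDataset(
        matrix=matrix,
        genes=genes,
        cells=cells,
        cell_type=meta["cell_type"].to_numpy(object),
        sample=meta["sample"].to_numpy(object),
        condition=condition,
        region=region,
    )
    counts = pd.Series(ds.cell_type).value_counts()
    logger.info("loaded %d cells x %d genes; cells per type: %s",
                ds.n_cells, ds.n_genes, counts.to_dict())
    return ds


def write_dataset(ds: ExpressionDataset, out_dir) -> None:
    """Write matrix.mtx + genes.tsv + metadata.tsv (inverse of load)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.csr_matrix(ds.matrix))
    (out / "genes.tsv").write_text("\n".join(ds.genes) + "\n")
    meta = pd.DataFrame(
        {
            "cell": ds.cells,
            "cell_type": ds.cell_type,
            "sample": ds.sample,
            "condition": [ds.condition[s] for s in ds.sample],
        }
    )
    if ds.region is not None:
        meta["region"] = [ds.region[s] for s in ds.sample]
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)


def check_group_balance(ds: ExpressionDataset) -> pd.DataFrame:
    """Advisory per-cell-type rank-sum test of per-sample cell counts.

    For each cell type the per-sample counts of the two condition groups are
    compared with a two-sided Wilcoxon rank-sum test; large p-values support
    the assumption that cell numbers are uniform between conditions.  A
    condition with fewer than two samples flags the report ``underpowered``
    rather than erroring — the check is advisory.
    """
    conds = ds.conditions
    if len(conds) != 2:
        raise DatasetError(f"need exactly two conditions, got {conds}")
    cond_a, cond_b = conds
    samples_by_cond = {c: sorted(s for s, cc in ds.condition.items() if cc == c) for c in conds}
    if min(len(v) for v in samples_by_cond.values()) == 0:
        raise DatasetError("a condition has no samples")
    underpowered = any(len(v) < 2 for v in samples_by_cond.values())

    counts = (
        pd.crosstab(pd.Series(ds.sample, name="sample"), pd.Series(ds.cell_type, name="cell_type"))
        .reindex(ds.samples, fill_value=0)
    )
    rows = []
    for ct in ds.cell_types:
        a = counts.loc[samples_by_cond[cond_a], ct].to_numpy(float) if ct in counts else np.zeros(0)
        b = counts.loc[samples_by_cond[cond_b], ct].to_numpy(float) if ct in counts else np.zeros(0)
        if underpowered or len(a) == 0 or len(b) == 0:
            p = np.nan
        elif np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
            p = 1.0
        else:
            method = "exact" if (max(len(a), len(b)) <= 10
                                 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
        rows.append({"cell_type": ct, "p_value": p,
                     "flag": "underpowered" if underpowered else "ok"})
    return pd.DataFrame(rows)
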