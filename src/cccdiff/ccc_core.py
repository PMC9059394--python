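"""Cell-type communication inference.

For every (sender cell type, receiver cell type, ligand-receptor
interaction) triple a mass-action communication strength is computed from
cell-type summary expression and assessed for significance by permuting
cell-type labels.  Significant strengths are then aggregated into
pathway-level scores, "information flow" (a pathway's score summed over all
cell pairs), and per-cell-type outgoing/incoming contributions.

Model
-----
Per cell type, gene expression is summarized by a 25%-truncated mean over
cells (arithmetic mean optional); genes expressed in fewer than 20% of the
cells of a type are zeroed for that type.  Complex expression is the
geometric mean over subunits, so a missing subunit nulls the interaction.
The strength of an interaction with ligand summary L and receptor summary R
is the Hill-type mass-action response

    P = (L * R') / (kh + L * R') * (1 + AG/(kh+AG)) * kh/(kh+AN)

where R' = R * (1 + CS/(kh+CS)) * kh/(kh+CI) folds in receiver-side
co-stimulatory (CS) and co-inhibitory (CI) co-receptor expression and
AG/AN are sender-side agonist/antagonist summaries (arithmetic mean over
the cofactor gene set).  Without cofactors the strength lies in [0, 1).

Significance: cell-type labels are shuffled (globally, or within a grouping
such as sample), the full pipeline including the expression-fraction filter
is recomputed, and p = (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset
from .lr_resource import GeneComplex, LRDatabase

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass
class HillParams:
    """Tunable constants of the mass-action strength model.

    ``kh`` is the half-saturation constant of the Hill response (strength
    0.5 exactly when L*R = kh, no cofactors); ``use_cofactors`` toggles
    agonist/antagonist/co-receptor modulation; ``n_perm`` and ``alpha``
    control the permutation test.
    """

    kh: float = 0.5
    use_cofactors: bool = True
    n_perm: int = 100
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.kh <= 0:
            raise ParameterError("kh must be positive")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")


@dataclass
class CellTypeProfile:
    """Per-cell-type summary expression and expression fractions."""

    mean_expr: pd.DataFrame  # cell_type x gene, filtered summary
    expr_fraction: pd.DataFrame  # cell_type x gene, fraction of cells > 0

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_expr.index)


@dataclass
class CommunicationTensor:
    """Strengths and permutation p-values per (sender, receiver, interaction)."""

    strength: np.ndarray  # (n_types, n_types, n_interactions)
    pval: np.ndarray
    cell_types: list[str]
    interactions: list[str]
    alpha: float
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pval = np.where(self.strength == 0, 1.0, self.pval)
        self.significant = self.pval < self.alpha


@dataclass
class PathwayScores:
    """Sum of significant interaction strengths per (sender, receiver, pathway)."""

    score: np.ndarray  # (n_types, n_types, n_pathways)
    cell_types: list[str]
    pathways: list[str]

    @property
    def detected(self) -> pd.Series:
        """Pathways with any nonzero score; the rest are "not detected"."""
        return pd.Series(
            self.score.sum(axis=(0, 1)) > 0, index=self.pathways, name="detected"
        )


# ---------------------------------------------------------------------------
# summaries


def _truncated_mean(block: np.ndarray, proportion: float) -> np.ndarray:
    """Mean of each column after dropping the lowest/highest ``proportion``."""
    n = block.shape[0]
    k = int(proportion * n)
    if n - 2 * k <= 0:
        k = 0
    srt = np.sort(block, axis=0)
    return srt[k : n - k].mean(axis=0)


def _profiles_from_labels(
    cells_by_genes: np.ndarray,
    labels: np.ndarray,
    cell_types: list[str],
    threshold: float,
    summary: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Summary and fraction matrices (n_types, n_genes) for given labels."""
    n_genes = cells_by_genes.shape[1]
    mean_expr = np.zeros((len(cell_types), n_genes))
    frac = np.zeros_like(mean_expr)
    for i, ct in enumerate(cell_types):
        block = cells_by_genes[labels == ct]
        if block.shape[0] == 0:
            continue
        frac[i] = (block > 0).mean(axis=0)
        if summary == "trimean":
            mean_expr[i] = _truncated_mean(block, 0.25)
        else:
            mean_expr[i] = block.mean(axis=0)
    mean_expr[frac < threshold] = 0.0
    return mean_expr, frac


def summarize_profiles(
    ds: ExpressionDataset,
    threshold: float = 0.2,
    summary: str = "trimean",
) -> CellTypeProfile:
    """Summarize expression per cell type with the low-fraction filter.

    ``summary`` is ``"trimean"`` (25%-truncated mean, the default) or
    ``"mean"``.  Any (cell type, gene) whose expression fraction falls below
    ``threshold`` has its summary forced to zero.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError("threshold must lie in [0, 1]")
    if summary not in ("trimean", "mean"):
        raise ParameterError(f"unknown summary {summary!r}")
    types = ds.cell_types
    mean_expr, frac = _profiles_from_labels(
        ds.matrix.T, ds.cell_type, types, threshold, summary
    )
    return CellTypeProfile(
        mean_expr=pd.DataFrame(mean_expr, index=types, columns=ds.genes),
        expr_fraction=pd.DataFrame(frac, index=types, columns=ds.genes),
    )


def complex_expression(
    profile: CellTypeProfile, cplx: GeneComplex, cell_type: str
) -> float:
    """Geometric mean of subunit summaries; zero if any subunit is absent."""
    values = []
    for gene in cplx.subunits:
        if gene in profile.mean_expr.columns:
            values.append(float(profile.mean_expr.at[cell_type, gene]))
        else:
            logger.warning("gene %s not in expression matrix; treated as 0", gene)
            values.append(0.0)
    arr = np.asarray(values)
    if np.any(arr == 0):
        return 0.0
    return float(arr.prod() ** (1.0 / len(arr)))


def interaction_strength(
    L: float,
    R: float,
    cofactor_terms: dict | None = None,
    params: HillParams | None = None,
) -> float:
    """Mass-action strength of a single interaction.

    ``cofactor_terms`` may supply ``agonist``/``antagonist`` (sender-side)
    and ``co_stimulatory``/``co_inhibitory`` (receiver-side) summary
    expression values; absent terms default to no modulation.
    """
    params = params or HillParams()
    if L < 0 or R < 0:
        raise ParameterError("expression summaries must be non-negative")
    terms = cofactor_terms or {}
    for v in terms.values():
        if v < 0:
            raise ParameterError("cofactor summaries must be non-negative")
    kh = params.kh
    if params.use_cofactors:
        cs = terms.get("co_stimulatory", 0.0)
        ci = terms.get("co_inhibitory", 0.0)
        R = R * (1 + cs / (kh + cs)) * (kh / (kh + ci))
    lr = L * R
    base = lr / (kh + lr)
    if params.use_cofactors:
        ag = terms.get("agonist", 0.0)
        an = terms.get("antagonist", 0.0)
        base *= (1 + ag / (kh + ag)) * (kh / (kh + an))
    return float(base)


# ---------------------------------------------------------------------------
# vectorized database machinery


class _DBArrays:
    """Padded index arrays mapping a database onto a gene-column layout.

    Column ``n_used`` is a sentinel: genes named in the database but absent
    from the matrix point there and read as zero expression.
    """

    def __init__(self, db: LRDatabase, gene_index: dict[str, int]):
        self.interaction_ids = [it.id for it in db.interactions]
        used: dict[int, int] = {}  # matrix row -> local column
        missing: set[str] = set()

        def local(gene: str) -> int:
            row = gene_index.get(gene)
            if row is None:
                missing.add(gene)
                return -1  # remapped to the sentinel column below
            return used.setdefault(row, len(used))

        lig = [[local(g) for g in it.ligand.subunits] for it in db.interactions]
        rec = [[local(g) for g in it.receptor.subunits] for it in db.interactions]
        ago = [[local(g) for g in it.agonists] for it in db.interactions]
        ant = [[local(g) for g in it.antagonists] for it in db.interactions]
        cos = [[local(g) for g in it.co_stimulatory] for it in db.interactions]
        coi = [[local(g) for g in it.co_inhibitory] for it in db.interactions]

        if missing:
            logger.warning(
                "%d database gene(s) absent from matrix, treated as zero "
                "expression: %s", len(missing), sorted(missing)[:10]
            )
        self.rows = np.array(sorted(used, key=used.get), dtype=int)
        self.sentinel = len(used)

        def finalize(lists):
            width = max((len(v) for v in lists), default=1) or 1
            idx = np.full((len(lists), width), self.sentinel, dtype=int)
            valid = np.zeros((len(lists), width), dtype=bool)
            for i, v in enumerate(lists):
                for j, g in enumerate(v):
                    valid[i, j] = True
                    idx[i, j] = self.sentinel if g < 0 else g
            return idx, valid

        self.lig_idx, self.lig_valid = finalize(lig)
        self.rec_idx, self.rec_valid = finalize(rec)
        self.ago_idx, self.ago_valid = finalize(ago)
        self.ant_idx, self.ant_valid = finalize(ant)
        self.cos_idx, self.cos_valid = finalize(cos)
        self.coi_idx, self.coi_valid = finalize(coi)

    @staticmethod
    def _geometric(P: np.ndarray, idx: np.ndarray, valid: np.ndarray) -> np.ndarray:
        """Geometric mean over valid subunits; (n_types, n_interactions)."""
        V = P[:, idx]  # (T, I, W)
        V = np.where(valid[None, :, :], V, 1.0)
        counts = valid.sum(axis=1)  # (I,)
        prod = V.prod(axis=2)
        with np.errstate(invalid="ignore"):
            out = np.where(prod > 0, prod ** (1.0 / np.maximum(counts, 1)), 0.0)
        out[:, counts == 0] = 0.0
        return out

    @staticmethod
    def _arithmetic(P: np.ndarray, idx: np.ndarray, valid: np.ndarray) -> np.ndarray:
        """Arithmetic mean over valid cofactor genes; 0 where the list is empty."""
        V = P[:, idx]
        V = np.where(valid[None, :, :], V, 0.0)
        counts = valid.sum(axis=1)
        total = V.sum(axis=2)
        return np.where(counts > 0, total / np.maximum(counts, 1), 0.0)

    def strengths(self, profile_used: np.ndarray, params: HillParams) -> np.ndarray:
        """Strength tensor (senders, receivers, interactions).

        ``profile_used`` is (n_types, n_used_genes); a zero sentinel column
        is appended internally.
        """
        P = np.concatenate(
            [profile_used, np.zeros((profile_used.shape[0], 1))], axis=1
        )
        kh = params.kh
        L = self._geometric(P, self.lig_idx, self.lig_valid)  # (T, I)
        R = self._geometric(P, self.rec_idx, self.rec_valid)
        if params.use_cofactors:
            cs = self._arithmetic(P, self.cos_idx, self.cos_valid)
            ci = self._arithmetic(P, self.coi_idx, self.coi_valid)
            R = R * (1 + cs / (kh + cs)) * (kh / (kh + ci))
        lr = L[:, None, :] * R[None, :, :]
        S = lr / (kh + lr)
        if params.use_cofactors:
            ag = self._arithmetic(P, self.ago_idx, self.ago_valid)
            an = self._arithmetic(P, self.ant_idx, self.ant_valid)
            S = S * ((1 + ag / (kh + ag)) * (kh / (kh + an)))[:, None, :]
        return S


def _permuted_labels(
    rng: np.random.Generator, labels: np.ndarray, groups: np.ndarray | None
) -> np.ndarray:
    """Shuffle cell-type labels globally or within each group."""
    out = labels.copy()
    if groups is None:
        rng.shuffle(out)
        return out
    for g in np.unique(groups):
        mask = groups == g
        sub = out[mask]
        rng.shuffle(sub)
        out[mask] = sub
    return out


def infer_communication(
    ds: ExpressionDataset,
    db: LRDatabase,
    params: HillParams | None = None,
    seed: int = 0,
    threshold: float = 0.2,
    summary: str = "trimean",
    perm_within: str | None = None,
) -> CommunicationTensor:
    """Full strength/p-value tensor over (sender, receiver, interaction).

    ``perm_within="sample"`` restricts label shuffling to each sample
    (the per-sample design); the default shuffles globally.  Strengths with
    p >= alpha stay in ``strength`` but are excluded from ``significant``.
    """
    params = params or HillParams()
    types = ds.cell_types
    if len(types) < 2:
        raise ParameterError("need at least 2 cell types")
    arrays = _DBArrays(db, ds.gene_index)
    cells_by_genes = np.ascontiguousarray(ds.matrix[arrays.rows].T)
    labels = ds.cell_type
    groups = ds.sample if perm_within == "sample" else None

    obs_profile, _ = _profiles_from_labels(
        cells_by_genes, labels, types, threshold, summary
    )
    observed = arrays.strengths(obs_profile, params)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(params.n_perm):
        perm = _permuted_labels(rng, labels, groups)
        prof, _ = _profiles_from_labels(cells_by_genes, perm, types, threshold, summary)
        exceed += arrays.strengths(prof, params) >= observed
    pval = (1.0 + exceed) / (1.0 + params.n_perm)
    return CommunicationTensor(
        strength=observed,
        pval=pval,
        cell_types=types,
        interactions=arrays.interaction_ids,
        alpha=params.alpha,
    )


def permutation_test(
    ds: ExpressionDataset,
    db: LRDatabase,
    triple: tuple[str, str, str],
    params: HillParams | None = None,
    seed: int = 0,
    **kwargs,
) -> float:
    """Permutation p-value for one (sender, receiver, interaction id) triple.

    Uses the add-one estimator p = (1 + #{permuted >= observed}) / (1 + n_perm)
    with an inclusive comparison, so p is never zero and ties count against
    significance (conservative).
    """
    tensor = infer_communication(ds, db, params=params, seed=seed, **kwargs)
    s = tensor.cell_types.index(triple[0])
    r = tensor.cell_types.index(triple[1])
    i = tensor.interactions.index(triple[2])
    return float(tensor.pval[s, r, i])


# ---------------------------------------------------------------------------
# aggregation


def aggregate_pathways(t: CommunicationTensor, db: LRDatabase) -> PathwayScores:
    """Per (sender, receiver, pathway) sum of *significant* strengths."""
    pathways = sorted(db.pathways)
    n_types = len(t.cell_types)
    score = np.zeros((n_types, n_types, len(pathways)))
    id_to_pos = {iid: k for k, iid in enumerate(t.interactions)}
    masked = np.where(t.significant, t.strength, 0.0)
    for p, pw in enumerate(pathways):
        cols = [id_to_pos[i] for i in db.pathways[pw] if i in id_to_pos]
        if cols:
            score[:, :, p] = masked[:, :, cols].sum(axis=2)
    ps = PathwayScores(score=score, cell_types=t.cell_types, pathways=pathways)
    undetected = [pw for pw, d in ps.detected.items() if not d]
    if undetected:
        logger.info("pathways not detected: %s", undetected)
    return ps


def count_strength_maps(t: CommunicationTensor) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cell pair: number of significant interactions and total strength."""
    counts = t.significant.sum(axis=2)
    totals = np.where(t.significant, t.strength, 0.0).sum(axis=2)
    idx = pd.Index(t.cell_types, name="sender")
    cols = pd.Index(t.cell_types, name="receiver")
    return (
        pd.DataFrame(counts, index=idx, columns=cols),
        pd.DataFrame(totals, index=idx, columns=cols),
    )


def information_flow(ps: PathwayScores) -> pd.Series:
    """Pathway score summed over all sender-receiver pairs."""
    return pd.Series(ps.score.sum(axis=(0, 1)), index=ps.pathways, name="flow")


def relative_flow(ps_a: PathwayScores, ps_b: PathwayScores) -> pd.DataFrame:
    """Normalized information-flow shares of two conditions per pathway.

    Pathways with flow in exactly one condition are labeled specific to it;
    pathways silent in both are dropped (logged).
    """
    flow_a = information_flow(ps_a)
    flow_b = information_flow(ps_b)
    universe = sorted(set(flow_a.index) | set(flow_b.index))
    fa = flow_a.reindex(universe, fill_value=0.0)
    fb = flow_b.reindex(universe, fill_value=0.0)
    total = fa + fb
    dropped = total[total == 0].index.tolist()
    if dropped:
        logger.info("pathways with zero flow in both conditions dropped: %s", dropped)
    keep = total > 0
    fa, fb, total = fa[keep], fb[keep], total[keep]
    label = np.where(
        fa == 0, "specific_to_B", np.where(fb == 0, "specific_to_A", "shared")
    )
    return pd.DataFrame(
        {
            "flow_A": fa,
            "flow_B": fb,
            "relative_A": fa / total,
            "relative_B": fb / total,
            "label": label,
        }
    )


def celltype_contributions(
    ps: PathwayScores, direction: str, relative: bool = False
) -> pd.DataFrame:
    """Cell-type x pathway outgoing (sum over receivers) or incoming
    (sum over senders) signaling; the relative form scales each pathway
    column to a maximum of 1."""
    if direction == "outgoing":
        mat = ps.score.sum(axis=1)
    elif direction == "incoming":
        mat = ps.score.sum(axis=0)
    else:
        raise ParameterError(f"direction must be outgoing/incoming, got {direction!r}")
    out = pd.DataFrame(mat, index=ps.cell_types, columns=ps.pathways)
    if relative:
        colmax = out.max(axis=0)
        out = out.divide(colmax.where(colmax > 0, 1.0), axis=1)
    return out
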