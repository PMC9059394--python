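"""Between-condition comparison of communication.

Two complementary designs are implemented.  In the *global* design all
cells of a condition are merged, communication is inferred once per
condition, and conditions are contrasted through per-cell-pair count and
strength differences plus a paired Wilcoxon signed-rank test over cell-pair
pathway scores.  In the *sample-by-sample* (pseudo-bulk) design inference
runs independently within every sample; per-sample pathway and L-R
strengths become the observations of two-sided Wilcoxon rank-sum tests
between the condition groups, with pathways detected in fewer than a
minimum number of samples removed first and Benjamini-Hochberg FDR applied
within each tested family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .ccc_core import (
    CommunicationTensor,
    HillParams,
    ParameterError,
    PathwayScores,
    aggregate_pathways,
    count_strength_maps,
    infer_communication,
)
from .expression_io import ExpressionDataset
from .lr_resource import LRDatabase

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shared test helpers


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= 10 observations and
    there are no ties; normal approximation with tie correction otherwise.
    A unit constant across all samples is degenerate and returns p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 10) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# global approach


@dataclass
class GlobalComparison:
    """Outputs of the merged two-group design."""

    condition_a: str
    condition_b: str
    tensor_a: CommunicationTensor
    tensor_b: CommunicationTensor
    scores_a: PathwayScores
    scores_b: PathwayScores
    count_diff: pd.DataFrame  # sender x receiver, A - B
    strength_diff: pd.DataFrame
    pathway_tests: pd.DataFrame  # pathway, p, direction


def _paired_pathway_test(
    scores_a: PathwayScores, scores_b: PathwayScores
) -> pd.DataFrame:
    """Two-sided signed-rank test per pathway, pairing identical (s, r)
    cell pairs of the two conditions (zero differences kept, zsplit)."""
    assert scores_a.pathways == scores_b.pathways
    assert scores_a.cell_types == scores_b.cell_types
    rows = []
    for p, pw in enumerate(scores_a.pathways):
        x = scores_a.score[:, :, p].ravel()
        y = scores_b.score[:, :, p].ravel()
        if np.all(x == y):
            pval = 1.0
        else:
            pval = float(stats.wilcoxon(x, y, zero_method="zsplit").pvalue)
        diff = float(x.sum() - y.sum())
        rows.append(
            {
                "pathway": pw,
                "flow_A": float(x.sum()),
                "flow_B": float(y.sum()),
                "p": pval,
                "direction": "up_in_A" if diff > 0 else ("down_in_A" if diff < 0 else "ns"),
            }
        )
    out = pd.DataFrame(rows)
    out.loc[out["p"] >= 0.05, "direction"] = "ns"
    return out


def global_compare(
    ds: ExpressionDataset,
    db: LRDatabase,
    params: HillParams | None = None,
    seed: int = 0,
    **infer_kwargs,
) -> GlobalComparison:
    """Merge cells per condition, infer communication in each, contrast.

    Cell types present in only one condition are excluded with a warning so
    both tensors live on the same (sender, receiver) grid.
    """
    params = params or HillParams()
    conds = ds.conditions
    if len(conds) != 2:
        raise ParameterError(f"need exactly two conditions, got {conds}")
    cond_a, cond_b = conds
    ds_a = ds.subset_condition(cond_a)
    ds_b = ds.subset_condition(cond_b)
    shared = sorted(set(ds_a.cell_types) & set(ds_b.cell_types))
    if len(shared) < 2:
        raise ParameterError("fewer than 2 cell types shared by both conditions")
    dropped = (set(ds_a.cell_types) | set(ds_b.cell_types)) - set(shared)
    if dropped:
        logger.warning("cell types present in only one condition excluded: %s",
                       sorted(dropped))
        ds_a = ds_a.subset_cells(np.isin(ds_a.cell_type, shared))
        ds_b = ds_b.subset_cells(np.isin(ds_b.cell_type, shared))

    # both conditions share the permutation seed: identical inputs then give
    # identical significance masks, so a self-comparison is exactly zero
    tensor_a = infer_communication(ds_a, db, params, seed=seed, **infer_kwargs)
    tensor_b = infer_communication(ds_b, db, params, seed=seed, **infer_kwargs)
    scores_a = aggregate_pathways(tensor_a, db)
    scores_b = aggregate_pathways(tensor_b, db)
    counts_a, totals_a = count_strength_maps(tensor_a)
    counts_b, totals_b = count_strength_maps(tensor_b)
    return GlobalComparison(
        condition_a=cond_a,
        condition_b=cond_b,
        tensor_a=tensor_a,
        tensor_b=tensor_b,
        scores_a=scores_a,
        scores_b=scores_b,
        count_diff=counts_a - counts_b,
        strength_diff=totals_a - totals_b,
        pathway_tests=_paired_pathway_test(scores_a, scores_b),
    )


# ---------------------------------------------------------------------------
# sample-by-sample approach


@dataclass
class SampleLevelScores:
    """Per-sample ("pseudo-bulk") pathway and L-R strength matrices.

    ``lr_scores`` columns are a (pathway, sender, receiver, interaction)
    MultiIndex so pathway-level filtering can drop L-R units consistently.
    """

    pathway_scores: pd.DataFrame  # sample x pathway
    lr_scores: pd.DataFrame  # sample x (pathway, sender, receiver, interaction)
    condition: dict[str, str]
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def detected(self) -> pd.DataFrame:
        return self.pathway_scores > 0

    @property
    def samples(self) -> list[str]:
        return list(self.pathway_scores.index)


def per_sample_scores(
    ds: ExpressionDataset,
    db: LRDatabase,
    params: HillParams | None = None,
    seed: int = 0,
    **infer_kwargs,
) -> SampleLevelScores:
    """One inference run per sample; scores stacked into sample matrices.

    A sample whose cells span fewer than two cell types cannot support
    communication inference; it gets a row of zeros and is flagged.
    """
    params = params or HillParams()
    samples = ds.samples
    pathways = sorted(db.pathways)
    seeds = np.random.SeedSequence(seed).spawn(len(samples))
    pw_rows: dict[str, pd.Series] = {}
    lr_rows: dict[str, dict] = {}
    flagged: list[str] = []
    for smp, sseq in zip(samples, seeds):
        sub = ds.subset_sample(smp)
        if len(sub.cell_types) < 2:
            logger.warning("sample %s has < 2 cell types; zero row", smp)
            flagged.append(smp)
            pw_rows[smp] = pd.Series(0.0, index=pathways)
            lr_rows[smp] = {}
            continue
        tensor = infer_communication(
            sub, db, params, seed=int(sseq.generate_state(1)[0] % (2**31)), **infer_kwargs
        )
        scores = aggregate_pathways(tensor, db)
        pw_rows[smp] = pd.Series(scores.score.sum(axis=(0, 1)), index=scores.pathways)
        pathway_of = {it.id: it.pathway for it in db.interactions}
        sig = np.where(tensor.significant, tensor.strength, 0.0)
        cells = {}
        for si, s_ct in enumerate(tensor.cell_types):
            for ri, r_ct in enumerate(tensor.cell_types):
                for ii, iid in enumerate(tensor.interactions):
                    v = sig[si, ri, ii]
                    if v > 0:
                        cells[(pathway_of[iid], s_ct, r_ct, iid)] = v
        lr_rows[smp] = cells

    pathway_scores = pd.DataFrame(pw_rows).T.reindex(samples).fillna(0.0)
    pathway_scores.index.name = "sample"
    all_cols = sorted({c for row in lr_rows.values() for c in row})
    lr = pd.DataFrame(
        [[lr_rows[s].get(c, 0.0) for c in all_cols] for s in samples],
        index=pd.Index(samples, name="sample"),
        columns=pd.MultiIndex.from_tuples(
            all_cols, names=["pathway", "sender", "receiver", "interaction"]
        )
        if all_cols
        else pd.MultiIndex.from_arrays(
            [[], [], [], []], names=["pathway", "sender", "receiver", "interaction"]
        ),
    )
    return SampleLevelScores(
        pathway_scores=pathway_scores,
        lr_scores=lr,
        condition=dict(ds.condition),
        flagged_samples=flagged,
    )


def filter_pathways(sls: SampleLevelScores, min_samples: int = 5) -> SampleLevelScores:
    """Remove pathways detected (score > 0) in fewer than ``min_samples``
    samples, pooling both condition groups; detection in exactly
    ``min_samples`` samples retains the pathway."""
    keep = sls.detected.sum(axis=0) >= min_samples
    kept = list(sls.pathway_scores.columns[keep])
    lr = sls.lr_scores
    if lr.shape[1]:
        lr = lr.loc[:, lr.columns.get_level_values("pathway").isin(kept)]
    logger.info("pathway filter: %d of %d retained (min_samples=%d)",
                len(kept), sls.pathway_scores.shape[1], min_samples)
    return SampleLevelScores(
        pathway_scores=sls.pathway_scores.loc[:, kept],
        lr_scores=lr,
        condition=sls.condition,
        flagged_samples=list(sls.flagged_samples),
    )


def _differential_table(
    matrix: pd.DataFrame, groups: dict[str, str], alpha: float
) -> pd.DataFrame:
    """Rank-sum + BH table for a sample x unit matrix (one test family)."""
    conds = sorted(set(groups.values()))
    if len(conds) != 2:
        raise ParameterError(f"need exactly two groups, got {conds}")
    cond_a, cond_b = conds
    in_a = [s for s in matrix.index if groups[s] == cond_a]
    in_b = [s for s in matrix.index if groups[s] == cond_b]
    if len(in_a) < 2 or len(in_b) < 2:
        raise ParameterError("both groups need >= 2 samples")
    A = matrix.loc[in_a].to_numpy(float)
    B = matrix.loc[in_b].to_numpy(float)
    positive = matrix.to_numpy(float)
    positive = positive[positive > 0]
    eps = (positive.min() * 1e-3) if positive.size else 1e-6
    logger.info("fold-change pseudocount eps = %g", eps)

    rows = []
    for j, unit in enumerate(matrix.columns):
        a, b = A[:, j], B[:, j]
        p = rank_sum_p(a, b)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        degenerate = np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0])
        rows.append(
            {
                "unit": unit,
                f"mean_{cond_a}": mean_a,
                f"mean_{cond_b}": mean_b,
                f"sd_{cond_a}": float(a.std(ddof=1)),
                f"sd_{cond_b}": float(b.std(ddof=1)),
                "fold_change": (mean_a + eps) / (mean_b + eps),
                "p": p,
                "degenerate": bool(degenerate),
            }
        )
    columns = ["unit", f"mean_{cond_a}", f"mean_{cond_b}", f"sd_{cond_a}",
               f"sd_{cond_b}", "fold_change", "p", "degenerate"]
    out = pd.DataFrame(rows, columns=columns)
    if out.empty:
        out["fdr"] = []
        out["direction"] = []
        return out
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    mean_diff = out[f"mean_{cond_a}"] - out[f"mean_{cond_b}"]
    out["direction"] = np.where(
        out["p"] >= alpha, "ns", np.where(mean_diff > 0, "up_in_A", "down_in_A")
    )
    return out


def sample_wilcoxon(
    sls: SampleLevelScores,
    groups: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Two-sided rank-sum tests on pseudo-bulk scores.

    Tests run per pathway and per (cell-pair, interaction) unit, each family
    receiving its own Benjamini-Hochberg correction.  ``groups`` defaults to
    the dataset's sample-to-condition map; passing an explicit map supports
    regrouping designs (e.g. balanced 4-vs-4 subsets).
    """
    groups = groups or sls.condition
    scores = sls.pathway_scores.loc[[s for s in sls.samples if s in groups]]
    lr = sls.lr_scores.loc[scores.index]
    result = {"pathways": _differential_table(scores, groups, alpha)}
    if lr.shape[1]:
        result["lr"] = _differential_table(lr, groups, alpha)
    else:
        result["lr"] = pd.DataFrame()
    return result


def pca_samples(sls: SampleLevelScores) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (unscaled) PCA of the sample x pathway score matrix.

    Returns per-sample coordinates (with the condition label attached) and
    the variance-explained fractions, which sum to 1.
    """
    X = sls.pathway_scores.to_numpy(float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ParameterError("PCA needs >= 3 samples and >= 2 pathways")
    centered = X - X.mean(axis=0)
    if not np.any(centered):
        raise ParameterError("rank-0 score matrix")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=sls.pathway_scores.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    frame["condition"] = [sls.condition.get(s, "NA") for s in frame.index]
    return frame, pca.explained_variance_ratio_


@dataclass
class RobustnessReport:
    """Stability of global strength differences under cell subsampling."""

    full_diff: pd.DataFrame
    mean_diff: pd.DataFrame
    sd_diff: pd.DataFrame
    correlations: pd.Series  # per-repetition Pearson r vs full-data diff


def subsample_robustness(
    ds: ExpressionDataset,
    db: LRDatabase,
    params: HillParams | None = None,
    frac: float = 0.5,
    reps: int = 10,
    seed: int = 0,
    **infer_kwargs,
) -> RobustnessReport:
    """Repeat the global comparison on random cell subsets.

    Each repetition draws ``frac`` of all cells without replacement, reruns
    the merged two-group inference, and records the per-cell-pair strength
    difference; the report gives the element mean and SD across repetitions
    and each repetition's Pearson correlation with the full-data
    differences.
    """
    if not 0 < frac <= 1:
        raise ParameterError("frac must lie in (0, 1]")
    if reps < 2:
        raise ParameterError("reps must be >= 2")
    params = params or HillParams()
    full = global_compare(ds, db, params, seed=seed, **infer_kwargs)
    full_diff = full.strength_diff
    rng = np.random.default_rng(seed)
    diffs = []
    cors = []
    for rep in range(reps):
        if frac == 1.0:
            # degenerate subsample: same cells, same inference seed
            sub, rep_seed = ds, seed
        else:
            n_keep = int(round(frac * ds.n_cells))
            chosen = rng.choice(ds.n_cells, size=n_keep, replace=False)
            mask = np.zeros(ds.n_cells, dtype=bool)
            mask[chosen] = True
            sub, rep_seed = ds.subset_cells(mask), int(rng.integers(2**31))
        cmp = global_compare(ds=sub, db=db, params=params,
                             seed=rep_seed, **infer_kwargs)
        d = cmp.strength_diff.reindex(
            index=full_diff.index, columns=full_diff.columns, fill_value=0.0
        )
        diffs.append(d)
        x = full_diff.to_numpy().ravel()
        y = d.to_numpy().ravel()
        if np.std(x) == 0 or np.std(y) == 0:
            cors.append(1.0 if np.allclose(x, y) else np.nan)
        else:
            cors.append(float(stats.pearsonr(x, y).statistic))
    stack = np.stack([d.to_numpy() for d in diffs])
    return RobustnessReport(
        full_diff=full_diff,
        mean_diff=pd.DataFrame(stack.mean(axis=0), index=full_diff.index,
                               columns=full_diff.columns),
        sd_diff=pd.DataFrame(stack.std(axis=0, ddof=1), index=full_diff.index,
                             columns=full_diff.columns),
        correlations=pd.Series(cors, name="pearson_r",
                               index=pd.RangeIndex(reps, name="rep")),
    )
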