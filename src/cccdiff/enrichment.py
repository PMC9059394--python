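"""Downstream gene-set statistics for dysregulated signaling genes.

Three classic procedures: hypergeometric overrepresentation (ORA) of a
query gene list against flat GO-style sets, Fisher exact overlap between
two curated lists (e.g. disorder risk-gene collections), and preranked
gene-set enrichment (GSEA) of fold-change-ranked genes with a gene-label
permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named flat gene sets plus the background universe.

    Set members outside the universe are intersected away at test time
    (logged), so sets may be curated against a broader annotation than the
    measured genes.
    """

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        if not self.sets or any(len(v) == 0 for v in self.sets.values()):
            raise ValueError("gene sets must be non-empty")
        if len(self.universe) == 0:
            raise ValueError("universe must be non-empty")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, genes...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3 and parts[0]:
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_gene_list(path) -> list[str]:
    """One gene symbol per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


# ---------------------------------------------------------------------------
# overrepresentation


def ora(
    query: list[str], collection: GeneSetCollection, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query list per gene set.

    With universe size N, set size K (after intersection with the
    universe), query size n and overlap k, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n); BH correction across sets.
    """
    universe = set(collection.universe)
    if not universe:
        raise ValueError("empty universe")
    q = set(query) & universe
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("%d query gene(s) outside universe dropped", dropped)
    if not q:
        raise ValueError("query is empty after intersection with universe")
    N, n = len(universe), len(q)
    rows = []
    for name, members in collection.sets.items():
        s = set(members) & universe
        k = len(q & s)
        K = len(s)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_cut
    return out.sort_values("p", ignore_index=True)


def overlap_test(
    list_a: list[str], list_b: list[str], universe: list[str]
) -> dict[str, float]:
    """Fisher exact test of the overlap between two gene lists.

    Builds the 2x2 table [[a, b], [c, d]] with a = |A∩B| inside the
    universe and returns the sample odds ratio (a*d)/(b*c), applying the
    Haldane 0.5 continuity correction when any cell is zero, plus the
    two-sided Fisher exact p.  An empty list after intersection is flagged
    and returns p = 1.
    """
    uni = set(universe)
    A = set(list_a) & uni
    B = set(list_b) & uni
    if len(uni) < len(A | B):
        raise ValueError("universe smaller than the union of the lists")
    if not A or not B:
        logger.warning("empty gene list after universe intersection")
        return {"a": 0, "b": len(A - B), "c": len(B - A),
                "d": len(uni - A - B), "odds_ratio": float("nan"),
                "p": 1.0, "flag": "empty_list"}
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(uni - A - B)
    flag = ""
    if a == len(A) == len(B) == len(uni):
        flag = "degenerate"
    table = np.array([[a, b], [c, d]], float)
    if (table == 0).any():
        table = table + 0.5
    odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p, "flag": flag}


# ---------------------------------------------------------------------------
# preranked GSEA


def enrichment_score(
    ranked_genes: list[str], scores: np.ndarray, members: set[str], weight: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    ``ranked_genes`` must be sorted by decreasing score.  Hits advance the
    running sum by |score|^weight (normalized over the set), misses retreat
    by 1/(N - Nh); the ES is the extremum of the running sum.
    """
    hit = np.array([g in members for g in ranked_genes])
    nh = int(hit.sum())
    n = len(ranked_genes)
    if nh == 0:
        return 0.0
    w = np.abs(scores) ** weight
    denom_hit = w[hit].sum()
    if denom_hit == 0:
        # all member scores are zero; fall back to unweighted steps
        step_hit = np.where(hit, 1.0 / nh, 0.0)
    else:
        step_hit = np.where(hit, w / denom_hit, 0.0)
    if n - nh == 0:
        # set covers the whole ranking: no miss steps exist, so measure the
        # deviation of the weighted hit accumulation from the uniform walk
        running = np.cumsum(step_hit) - np.arange(1, n + 1) / n
    else:
        step_miss = np.where(hit, 0.0, 1.0 / (n - nh))
        running = np.cumsum(step_hit - step_miss)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranking: pd.Series,
    sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    fdr_cut: float = 0.25,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranking`` maps genes to scores (e.g. expression fold changes); the
    null permutes gene labels, equivalent to drawing random same-size sets
    from the ranking.  NES = ES / mean(|null ES| of the same sign); FDR
    follows the standard pooled positive/negative-null procedure.  Sets
    with fewer than ``min_size`` ranked members are skipped (logged).
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking genes must be unique")
    ranking = ranking.sort_values(ascending=False)
    genes = list(ranking.index)
    scores = ranking.to_numpy(float)
    rng = np.random.default_rng(seed)

    kept: dict[str, set[str]] = {}
    for name, members in sets.items():
        inside = set(members) & set(genes)
        if len(inside) < max(min_size, 1):
            logger.info("set %s skipped: %d ranked member(s)", name, len(inside))
            continue
        kept[name] = inside
    if not kept:
        return pd.DataFrame(
            columns=["set", "size", "es", "nes", "p", "fdr", "significant"]
        )

    es_obs = {name: enrichment_score(genes, scores, m, weight) for name, m in kept.items()}
    null_es: dict[str, np.ndarray] = {}
    gene_arr = np.array(genes, dtype=object)
    for name, members in kept.items():
        size = len(members)
        vals = np.empty(n_perm)
        for b in range(n_perm):
            random_set = set(rng.choice(gene_arr, size=size, replace=False))
            vals[b] = enrichment_score(genes, scores, random_set, weight)
        null_es[name] = vals

    def _nes(es: float, null: np.ndarray) -> float:
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same).mean() if same.size else np.nan
        return es / denom if denom and not np.isnan(denom) else np.nan

    rows = []
    for name, es in es_obs.items():
        null = null_es[name]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + max(len(same), 1))
        rows.append({"set": name, "size": len(kept[name]), "es": es,
                     "nes": _nes(es, null), "p": float(p)})
    out = pd.DataFrame(rows)

    # pooled-null FDR on NES, positive and negative tails separately
    pooled = np.concatenate(
        [np.array([_nes(v, null_es[name]) for v in null_es[name]])
         for name in kept]
    )
    pooled = pooled[~np.isnan(pooled)]
    obs_nes = out["nes"].to_numpy()
    fdrs = []
    for nes in obs_nes:
        if np.isnan(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            null_frac = np.mean(pooled[pooled >= 0] >= nes) if np.any(pooled >= 0) else 0.0
            obs_frac = np.mean(obs_nes[obs_nes >= 0] >= nes)
        else:
            null_frac = np.mean(pooled[pooled < 0] <= nes) if np.any(pooled < 0) else 0.0
            obs_frac = np.mean(obs_nes[obs_nes < 0] <= nes)
        fdrs.append(min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan)
    out["fdr"] = fdrs
    out["significant"] = out["fdr"] < fdr_cut
    return out.sort_values("p", ignore_index=True)
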