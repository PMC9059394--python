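"""Benchmark scenarios measuring the pipeline's statistical properties.

Each function builds its own synthetic inputs with planted ground truth,
runs the relevant pipeline stage from scratch, and returns summary
metrics: oracle agreement of the elementary tests, closed-form strength
checks, conservation of information flow, null calibration of the
permutation and pseudo-bulk tests, detection power and end-to-end recovery
under the emulated 13-vs-10 study design, NMF pattern recovery, filter
exactness, and spatial co-expression dominance.

Problem sizes are chosen to finish on a desktop in minutes while leaving
the statistical targets well-determined; they are documented per function.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .ccc_core import (
    HillParams,
    aggregate_pathways,
    infer_communication,
    information_flow,
    interaction_strength,
    summarize_profiles,
)
from .differential import filter_pathways, per_sample_scores, rank_sum_p, sample_wilcoxon
from .enrichment import GeneSetCollection, ora, overlap_test
from .expression_io import ExpressionDataset
from .patterns import detect_patterns, select_k
from .spatial import coexpression_test, lr_spatial_correlation, random_pair_null
from .synthetic import (
    PlantedSignal,
    SimConfig,
    default_study_config,
    generate_dataset,
    generate_spatial,
    generate_toy_db,
)

MAX_SEED = 2**31


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % MAX_SEED]


# ---------------------------------------------------------------------------
# 1. elementary-test oracles


def _enumerate_ranksum(a, b) -> float:
    pooled = sorted(list(a) + list(b))
    pos = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(pos[v] for v in a)
    sums = [sum(c) for c in combinations(range(1, len(pooled) + 1), len(a))]
    lo = sum(s <= obs for s in sums) / len(sums)
    hi = sum(s >= obs for s in sums) / len(sums)
    return min(1.0, 2 * min(lo, hi))


def wilcoxon_oracle_agreement(seed: int, n_instances: int = 200) -> dict:
    """Exact rank-sum p versus full enumeration on random tie-free groups."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_instances):
        n, m = rng.integers(2, 7, size=2)
        vals = rng.permutation(rng.normal(0, 10, int(n + m)))
        a, b = vals[:n], vals[n:]
        max_err = max(max_err, abs(rank_sum_p(a, b) - _enumerate_ranksum(a, b)))
    return {"value": max_err, "n": n_instances}


def hypergeometric_oracle_agreement(seed: int) -> dict:
    """ORA/Fisher p versus brute-force enumeration for universes <= 12."""
    max_err = 0.0
    cases = 0
    for N in (8, 10, 12):
        uni = [f"g{i}" for i in range(N)]
        for K in (2, N // 2):
            col = GeneSetCollection({"s": uni[:K]}, uni)
            for n in (2, 4):
                for k in range(min(K, n) + 1):
                    query = uni[:k] + uni[K : K + (n - k)]
                    p = ora(query, col)["p"].iloc[0]
                    hits = sum(
                        1
                        for combo in combinations(range(N), n)
                        if sum(x < K for x in combo) >= k
                    )
                    oracle = hits / len(list(combinations(range(N), n)))
                    max_err = max(max_err, abs(p - oracle))
                    cases += 1
    # Fisher p against the hypergeometric identity on one explicit table
    out = overlap_test(
        [f"g{i}" for i in range(10)],
        [f"g{i}" for i in range(5, 25)],
        [f"g{i}" for i in range(100)],
    )
    rv = stats.hypergeom(100, 10, 20)
    p_obs = rv.pmf(5)
    oracle = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p_obs + 1e-12)
    max_err = max(max_err, abs(out["p"] - oracle))
    return {"value": max_err, "n": cases + 1}


# ---------------------------------------------------------------------------
# 2. closed-form strength checks


def closed_form_error() -> dict:
    """Largest deviation of the strength model from its closed forms."""
    errs = [
        abs(interaction_strength(1.0, 0.5) - 0.5),
        abs(interaction_strength(1.0, 1.0) - 2 / 3),
    ]
    # complex expression {2, 8} -> geometric mean 4, via a constant dataset
    from .lr_resource import GeneComplex

    values = np.array([[2.0] * 6, [8.0] * 6])
    ds = ExpressionDataset(
        matrix=values,
        genes=["a", "b"],
        cells=[f"c{i}" for i in range(6)],
        cell_type=np.array(["T"] * 6, object),
        sample=np.array(["s"] * 6, object),
        condition={"s": "case"},
    )
    from .ccc_core import complex_expression

    prof = summarize_profiles(ds, threshold=0.0)
    errs.append(abs(complex_expression(prof, GeneComplex("X", ("a", "b")), "T") - 4.0))
    return {"value": max(errs), "n": len(errs)}


# ---------------------------------------------------------------------------
# 3. conservation


def flow_conservation_error(seed: int, n_runs: int = 3) -> dict:
    """|Σ_p flow(p) − Σ significant strengths| over synthetic runs."""
    seeds = _spawn(seed, 2 * n_runs)
    worst = 0.0
    for i in range(n_runs):
        db = generate_toy_db(4, 2, seed=seeds[i])
        types = ("A", "B", "C", "D")
        sigs = [PlantedSignal(f"PW{j:02d}", types[j % 4], types[(j + 1) % 4], 1.0)
                for j in range(4)]
        cfg = SimConfig(n_genes=60, cell_types=types, n_case=2, n_control=2,
                        cells_per_sample_per_type=(25, 35), db=db,
                        planted_signals=sigs, seed=seeds[n_runs + i])
        ds, _ = generate_dataset(cfg)
        tensor = infer_communication(ds, db, HillParams(n_perm=30), seed=seeds[i])
        ps = aggregate_pathways(tensor, db)
        total = np.where(tensor.significant, tensor.strength, 0.0).sum()
        worst = max(worst, abs(information_flow(ps).sum() - total))
    return {"value": worst, "n": n_runs}


# ---------------------------------------------------------------------------
# 4. null calibration


def permutation_uniformity(seed: int, n_datasets: int = 10) -> dict:
    """KS p-value of permutation p-values against Uniform(0,1).

    Exchangeable data: one sample, five cell types drawn from the same
    expression distribution (all genes well expressed, so no triple is
    nulled by the fraction filter); 50 triples per dataset.
    """
    seeds = _spawn(seed, 3 * n_datasets)
    ps = []
    for i in range(n_datasets):
        db = generate_toy_db(1, 2, seed=seeds[i])
        cfg = SimConfig(
            n_genes=20, cell_types=tuple("ABCDE"), n_case=1, n_control=1,
            cells_per_sample_per_type=(40, 40), db=db, planted_signals=[],
            db_background_level=1.0, baseline_log_mean=0.7, baseline_log_sd=0.3,
            seed=seeds[n_datasets + i],
        )
        ds, _ = generate_dataset(cfg)
        ds = ds.subset_sample(ds.samples[0])
        tensor = infer_communication(
            ds, db, HillParams(n_perm=100), seed=seeds[2 * n_datasets + i]
        )
        ps.append(tensor.pval.ravel())
    pooled = np.concatenate(ps)
    return {"value": float(stats.kstest(pooled, "uniform").pvalue), "n": pooled.size}


def pathway_test_type1(seed: int, n_reps: int = 20, n_pathways: int = 50) -> dict:
    """Rejection rate of the pseudo-bulk pathway test on null data.

    Every pathway has an active route (so scores are continuous) but no
    condition effect; 13 vs 10 samples as in the emulated design.
    """
    seeds = _spawn(seed, 3 * n_reps)
    types = tuple("ABCD")
    pairs = [(a, b) for a in types for b in types if a != b]
    pvals = []
    for rep in range(n_reps):
        db = generate_toy_db(n_pathways, 2, seed=seeds[rep])
        sigs = [PlantedSignal(f"PW{i:02d}", *pairs[i % len(pairs)], 1.0, "case")
                for i in range(n_pathways)]
        cfg = SimConfig(n_genes=20 + len(db.genes), cell_types=types,
                        n_case=13, n_control=10,
                        cells_per_sample_per_type=(30, 50), db=db,
                        planted_signals=sigs, seed=seeds[n_reps + rep])
        ds, _ = generate_dataset(cfg)
        sls = per_sample_scores(ds, db, HillParams(n_perm=100),
                                seed=seeds[2 * n_reps + rep])
        tab = sample_wilcoxon(filter_pathways(sls))["pathways"]
        pvals.extend(tab["p"].tolist())
    pvals = np.asarray(pvals)
    return {"value": float((pvals < 0.05).mean()), "n": int(pvals.size)}


# ---------------------------------------------------------------------------
# 5. parameter recovery


def detection_power(seed: int, n_reps: int = 100) -> dict:
    """Power of the pseudo-bulk design for a planted ligand fold-change 2.

    13 vs 10 samples, sample noise SD 0.25, one differential pathway among
    four (the rest active but null), ~100 cells per type per sample.
    """
    seeds = _spawn(seed, 2 * n_reps)
    types = ("A", "B", "C", "D")
    detected = 0
    for rep in range(n_reps):
        db = generate_toy_db(4, 3, seed=2)
        sigs = [PlantedSignal("PW00", "A", "B", 2.0, "case"),
                PlantedSignal("PW01", "B", "C", 1.0, "case"),
                PlantedSignal("PW02", "C", "D", 1.0, "case"),
                PlantedSignal("PW03", "D", "A", 1.0, "case")]
        cfg = SimConfig(n_genes=150, cell_types=types, n_case=13, n_control=10,
                        cells_per_sample_per_type=(80, 120), db=db,
                        planted_signals=sigs, seed=seeds[rep])
        ds, _ = generate_dataset(cfg)
        sls = per_sample_scores(ds, db, HillParams(n_perm=100),
                                seed=seeds[n_reps + rep])
        tab = sample_wilcoxon(filter_pathways(sls))["pathways"].set_index("unit")
        detected += bool(tab.loc["PW00", "p"] < 0.05)
    return {"value": detected / n_reps, "n": n_reps}


def end_to_end_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Full-pipeline recovery under the reference study configuration.

    5 differential pathways (ligand fold-change 2) among 30, 17 cell types,
    13 vs 10 samples, ~50 cells/type/sample.  A seed succeeds when >= 4 of
    5 planted pathways reach p < 0.05 and <= 2 of the 25 null pathways are
    called.  Returns the success fraction plus mean recall/false positives.
    """
    seeds = _spawn(seed, 3 * n_seeds)
    successes, recalls, fps = [], [], []
    for i in range(n_seeds):
        db = generate_toy_db(30, 3, seed=7)
        cfg = default_study_config(seed=seeds[i], db=db)
        ds, truth = generate_dataset(cfg)
        sls = per_sample_scores(ds, db, HillParams(n_perm=100),
                                seed=seeds[n_seeds + i])
        tab = sample_wilcoxon(filter_pathways(sls))["pathways"].set_index("unit")
        planted = set(truth.loc[truth["differential"], "pathway"])
        hits = sum(1 for pw in planted
                   if pw in tab.index and tab.loc[pw, "p"] < 0.05)
        fp = sum(1 for pw in tab.index
                 if pw not in planted and tab.loc[pw, "p"] < 0.05)
        successes.append(hits >= 4 and fp <= 2)
        recalls.append(hits / len(planted))
        fps.append(fp)
    return {
        "value": float(np.mean(successes)),
        "n": n_seeds,
        "mean_recall": float(np.mean(recalls)),
        "mean_false_positives": float(np.mean(fps)),
    }


# ---------------------------------------------------------------------------
# 6. pattern recovery


def pattern_recovery(seed: int, n_seeds: int = 20) -> dict:
    """NMF rank selection and block assignment on 2-block matrices.

    10 cell types x 12 pathways, two planted blocks, noise SD 8% of the
    signal.  Reports the fraction of seeds with selected k = 2 and
    assignment ARI >= 0.9.
    """
    from sklearn.metrics import adjusted_rand_score

    seeds = _spawn(seed, n_seeds)
    ok_k, ok_ari = 0, 0
    for s in seeds:
        rng = np.random.default_rng(s)
        labels = np.array([0] * 5 + [1] * 5)
        M = np.zeros((10, 12))
        M[labels == 0, :6] = 1.0
        M[labels == 1, 6:] = 1.0
        M = np.clip(M + rng.normal(0, 0.08, M.shape), 0, None)
        frame = pd.DataFrame(M, index=[f"ct{i}" for i in range(10)],
                             columns=[f"p{j}" for j in range(12)])
        k, _ = select_k(frame, k_range=range(2, 6), runs_per_k=30, seed=s)
        pat = detect_patterns(frame, 2, seed=s)
        assign = pat.cell_loadings.to_numpy().argmax(axis=1)
        ok_k += k == 2
        ok_ari += adjusted_rand_score(labels, assign) >= 0.9
    return {"value": min(ok_k, ok_ari) / n_seeds, "n": n_seeds,
            "k_correct": ok_k / n_seeds, "ari_ok": ok_ari / n_seeds}


# ---------------------------------------------------------------------------
# 7. exact filters


def filter_exactness(seed: int) -> dict:
    """Boundary behavior of the two hard filters (1 = both exact).

    A pathway detected in 4 of 23 samples must be removed and one detected
    in 5 retained; a gene expressed in 15% of a type's cells must
    contribute zero strength.
    """
    samples = [f"s{i}" for i in range(23)]
    cond = {s: ("case" if i < 13 else "control") for i, s in enumerate(samples)}
    ok = []
    for n_det, kept in ((4, False), (5, True)):
        mat = pd.DataFrame(0.0, index=samples, columns=["P"])
        mat.iloc[:n_det, 0] = 1.0
        from .differential import SampleLevelScores

        empty = pd.DataFrame(index=mat.index, columns=pd.MultiIndex.from_arrays(
            [[], [], [], []],
            names=["pathway", "sender", "receiver", "interaction"]))
        sls = SampleLevelScores(pathway_scores=mat, lr_scores=empty, condition=cond)
        out = filter_pathways(sls, min_samples=5)
        ok.append(("P" in out.pathway_scores.columns) == kept)

    # 20% expression filter: 3 of 20 cells expressing -> zero summary
    values = np.zeros((1, 40))
    values[0, :3] = 5.0  # type T: 15% expressing
    values[0, 20:] = 2.0  # type U: all expressing
    ds = ExpressionDataset(
        matrix=values,
        genes=["g"],
        cells=[f"c{i}" for i in range(40)],
        cell_type=np.array(["T"] * 20 + ["U"] * 20, object),
        sample=np.array(["s"] * 40, object),
        condition={"s": "case"},
    )
    prof = summarize_profiles(ds, threshold=0.2)
    ok.append(prof.mean_expr.at["T", "g"] == 0.0)
    ok.append(prof.mean_expr.at["U", "g"] > 0.0)
    return {"value": float(all(ok)), "n": len(ok)}


# ---------------------------------------------------------------------------
# 8. spatial dominance


def spatial_dominance(seed: int, n_pairs: int = 50, n_spots: int = 200) -> dict:
    """One-sided Mann-Whitney p: planted rho = 0.5 pairs versus random pairs."""
    s1, s2 = _spawn(seed, 2)
    pairs = [(f"SG{2*i:04d}", f"SG{2*i+1:04d}", 0.5) for i in range(n_pairs)]
    sp = generate_spatial(n_genes=3 * n_pairs, n_spots=n_spots,
                          planted_pairs=pairs, seed=s1)
    true_r = lr_spatial_correlation(sp, [(l, r) for l, r, _ in pairs])["r"]
    null = random_pair_null(sp, 400, seed=s2,
                            exclude={(l, r) for l, r, _ in pairs})
    res = coexpression_test(true_r.to_numpy(), null)
    return {"value": res["mannwhitney_p"], "n": n_pairs,
            "ks_stat": res["ks_stat"]}
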