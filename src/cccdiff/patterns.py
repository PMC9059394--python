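"""Latent communication patterns via non-negative matrix factorization.

Cell types that send (or receive) similar sets of signaling pathways are
grouped by factoring the cell-type x pathway signaling matrix as M ~ W H
with W, H >= 0.  The number of patterns k is chosen from consensus
clustering diagnostics: for each candidate k, repeated NMF runs from random
initializations yield a co-clustering consensus matrix whose cophenetic
correlation and mean silhouette quantify stability.  The selection rule is
the largest k at which both metrics hold at least 95% of their k = 2 value,
falling back to the k with maximal cophenetic correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .ccc_core import ParameterError, PathwayScores

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class CommunicationPatterns:
    """NMF loadings linking cell types to pathway groups."""

    direction: str  # outgoing | incoming
    k: int
    cell_loadings: pd.DataFrame  # cell_type x k, rows sum to 1
    pathway_loadings: pd.DataFrame  # k x pathway, non-negative
    diagnostics: pd.DataFrame | None = None
    converged: bool = True

    def top_members(self, n: int = 3) -> pd.DataFrame:
        """Leading cell types and pathways of each pattern."""
        rows = []
        for pat in self.cell_loadings.columns:
            cells = self.cell_loadings[pat].nlargest(n).index.tolist()
            pws = self.pathway_loadings.loc[pat].nlargest(n).index.tolist()
            rows.append({"pattern": pat, "top_cell_types": ",".join(cells),
                         "top_pathways": ",".join(pws)})
        return pd.DataFrame(rows)


def build_signaling_matrix(ps: PathwayScores, direction: str) -> pd.DataFrame:
    """Cell-type x pathway matrix for one signaling direction.

    Outgoing sums scores over receivers, incoming over senders; each
    detected pathway column is scaled to a maximum of 1 and undetected
    (all-zero) pathways are dropped.
    """
    if direction == "outgoing":
        mat = ps.score.sum(axis=1)
    elif direction == "incoming":
        mat = ps.score.sum(axis=0)
    else:
        raise ParameterError(f"direction must be outgoing/incoming, got {direction!r}")
    frame = pd.DataFrame(mat, index=ps.cell_types, columns=ps.pathways)
    frame = frame.loc[:, frame.max(axis=0) > 0]
    if frame.shape[1] == 0:
        raise ParameterError("no detected pathway; cannot build signaling matrix")
    return frame / frame.max(axis=0)


def nmf(
    M: np.ndarray, k: int, seed: int, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Multiplicative-update NMF (Frobenius loss).

    W and H are initialized from seeded uniform (0, 1] draws scaled by the
    matrix mean.  Returns W (n x k), H (k x m), the reconstruction-error
    trajectory (non-increasing), and a convergence flag.
    """
    M = np.asarray(M, float)
    if np.any(M < 0):
        raise ParameterError("NMF input must be non-negative")
    rng = np.random.default_rng(seed)
    scale = max(M.mean(), _EPS)
    n, m = M.shape
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale
    errors = [float(np.linalg.norm(M - W @ H))]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ M) / (W.T @ W @ H + _EPS)
        W *= (M @ H.T) / (W @ H @ H.T + _EPS)
        err = float(np.linalg.norm(M - W @ H))
        errors.append(err)
        if abs(errors[-2] - err) <= tol * max(errors[0], _EPS):
            converged = True
            break
    return W, H, errors, converged


def _consensus_matrix(M: np.ndarray, k: int, runs: int, rng: np.random.Generator) -> np.ndarray:
    n = M.shape[0]
    C = np.zeros((n, n))
    for _ in range(runs):
        W, _, _, _ = nmf(M, k, seed=int(rng.integers(2**31)))
        labels = W.argmax(axis=1)
        C += labels[:, None] == labels[None, :]
    return C / runs


def _consensus_diagnostics(C: np.ndarray, k: int) -> tuple[float, float]:
    """Cophenetic correlation and mean silhouette of a consensus matrix."""
    n = C.shape[0]
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    if condensed.std() < 1e-12:
        # flat distances: everything always (or never) co-clusters
        coph = 1.0 if condensed.max() < 1e-12 else 0.0
    else:
        coph = float(cophenet(Z, condensed)[0])
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= n:
        sil = 0.0
    else:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return coph, sil


def select_k(
    M: pd.DataFrame | np.ndarray,
    k_range: range | list[int] | None = None,
    runs_per_k: int = 30,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of patterns from consensus-clustering stability.

    For each candidate k, ``runs_per_k`` NMF runs build a consensus
    co-clustering matrix; its cophenetic correlation and mean silhouette
    are recorded.  Chosen k = the largest candidate at which both metrics
    stay >= 95% of their k = 2 value; if no candidate qualifies, the k with
    maximal cophenetic correlation.
    """
    X = np.asarray(M, float)
    if np.allclose(X, X.flat[0]):
        raise ParameterError("constant matrix: patterns are undefined")
    n = X.shape[0]
    if k_range is None:
        k_range = range(2, 11)
    ks = [k for k in k_range if 2 <= k < n]
    if not ks:
        raise ParameterError(f"no candidate k in range for {n} rows")
    rng = np.random.default_rng(seed)
    records = []
    for k in ks:
        C = _consensus_matrix(X, k, runs_per_k, rng)
        coph, sil = _consensus_diagnostics(C, k)
        records.append({"k": k, "cophenetic": coph, "silhouette": sil})
    diag = pd.DataFrame(records)
    ref = diag.iloc[0]
    ok = (diag["cophenetic"] >= 0.95 * ref["cophenetic"]) & (
        diag["silhouette"] >= 0.95 * ref["silhouette"]
    )
    if ok.any():
        chosen = int(diag.loc[ok, "k"].max())
    else:
        chosen = int(diag.loc[diag["cophenetic"].idxmax(), "k"])
    logger.info("selected k = %d\n%s", chosen, diag.to_string(index=False))
    return chosen, diag


def detect_patterns(
    M: pd.DataFrame,
    k: int,
    seed: int = 0,
    direction: str = "outgoing",
    diagnostics: pd.DataFrame | None = None,
) -> CommunicationPatterns:
    """Final NMF fit at a chosen k with row-normalized cell loadings.

    Rows of the cell-loading matrix are scaled to sum to 1 so each cell
    type distributes unit weight across patterns; a cell type with no
    signal at all receives a uniform loading.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    W, H, errors, converged = nmf(M.to_numpy(float), k, seed=seed)
    if not converged:
        logger.warning("NMF did not converge within max iterations")
    rowsum = W.sum(axis=1, keepdims=True)
    W_norm = np.where(rowsum > 0, W / np.maximum(rowsum, _EPS), 1.0 / k)
    pattern_names = [f"pattern_{i + 1}" for i in range(k)]
    return CommunicationPatterns(
        direction=direction,
        k=k,
        cell_loadings=pd.DataFrame(W_norm, index=M.index, columns=pattern_names),
        pathway_loadings=pd.DataFrame(H, index=pattern_names, columns=M.columns),
        diagnostics=diagnostics,
        converged=converged,
    )
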