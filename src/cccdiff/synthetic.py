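"""Synthetic expression, database and spatial fixtures with planted truth.

The generator emulates the snRNA-seq study design this pipeline targets:
two brain-sample groups (13 condition vs 10 control samples by default),
17 annotated cell types, negative-binomial counts library-normalized and
log2(1+x)-transformed, and condition-specific ligand-receptor signaling
planted as ground truth.  Counts first, normalization second, so zeros are
realistic and the expression-fraction filter is genuinely exercised.

Ligand and receptor genes are cell-type-specific, as in cortical tissue:
outside their planted routes, database genes sit at a low background level
(below the expression-fraction filter by default), so communication along
a pathway is carried by its designated route rather than by diffuse
expression.  A planted signal designates a (pathway, sender, receiver)
route: the pathway's ligand genes are expressed in the sender type (both
conditions) and its receptor genes in the receiver type; the condition
effect multiplies the sender's ligand expression by ``fold_change`` in the
designated condition only.  With ``fold_change = 1`` the route is active
but null — useful for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset
from .lr_resource import GeneComplex, LRDatabase, LRInteraction
from .spatial import SpatialDataset

#: Cell-type labels mirroring the 17 cortical populations of the target study.
DEFAULT_CELL_TYPES = (
    "AST-FB", "AST-PP", "Endothelial", "IN-PV", "IN-SST", "IN-SV2C", "IN-VIP",
    "L2/3", "L4", "L5/6", "L5/6-CC", "Microglia", "Neu-NRGN-I", "Neu-NRGN-II",
    "Neu-mat", "OPC", "Oligodendrocytes",
)

DEFAULT_LAYERS = ("L1", "L2", "L3", "L4", "L5", "L6", "WM")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSignal:
    """Ground-truth differential communication along one pathway route."""

    pathway: str
    sender: str
    receiver: str
    fold_change: float = 2.0  # ligand multiplier in `condition` samples
    condition: str = "case"
    ligand_boost: float = 1.0  # sender-type ligand level relative to baseline
    receptor_boost: float = 1.0  # receiver-type receptor level, both conditions

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ConfigError("fold_change must be positive")


@dataclass
class SimConfig:
    """Study-design parameters of the expression generator.

    Defaults follow the emulated study: 13 case vs 10 control samples,
    17 cell types, ~50 cells per type per sample, multiplicative
    per-sample-per-gene noise with SD 0.25, negative-binomial counts.
    """

    n_genes: int = 200
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_case: int = 13
    n_control: int = 10
    condition_labels: tuple[str, str] = ("case", "control")
    cells_per_sample_per_type: tuple[int, int] = (35, 65)
    baseline_log_mean: float = 0.0  # log of NB mean counts ~ lognormal
    baseline_log_sd: float = 0.5
    nb_dispersion: float = 10.0  # NB size; var = mu + mu^2/size
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    sample_effect_sd: float = 0.25
    db: LRDatabase | None = None
    # database genes outside their planted routes sit at this fraction of
    # baseline; kept well under the 20% expression filter even for genes
    # with a high baseline mean, so ligand/receptor expression is
    # cell-type-specific as in real cortex
    db_background_level: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("both conditions need >= 1 sample")
        lo, hi = self.cells_per_sample_per_type
        if lo < 1 or hi < lo:
            raise ConfigError("invalid cells_per_sample_per_type range")
        if len(self.condition_labels) != 2:
            raise ConfigError("exactly two conditions")


def generate_toy_db(
    n_pathways: int,
    interactions_per_pathway: int = 2,
    with_complexes: bool = False,
    with_cofactors: bool = False,
    seed: int = 0,
    universe: list[str] | None = None,
) -> LRDatabase:
    """Pathway-structured toy interaction database.

    Gene symbols are synthesized deterministically (``L00a``/``R00a`` style)
    unless a ``universe`` is supplied, in which case genes are drawn from it
    without replacement (error if it is too small).  ``with_complexes``
    makes every second receptor a two-subunit complex; ``with_cofactors``
    attaches one agonist and one antagonist gene per pathway.
    """
    if n_pathways < 1:
        raise ConfigError("n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    needed = n_pathways * interactions_per_pathway * (3 if with_complexes else 2)
    needed += 2 * n_pathways if with_cofactors else 0
    pool: list[str] | None = None
    if universe is not None:
        if len(universe) < needed:
            raise ConfigError(
                f"universe of {len(universe)} genes cannot supply {needed}"
            )
        pool = list(rng.choice(universe, size=needed, replace=False))

    def next_gene(default: str) -> str:
        return pool.pop() if pool is not None else default

    interactions = []
    for p in range(n_pathways):
        pw = f"PW{p:02d}"
        ago = next_gene(f"AG{p:02d}") if with_cofactors else None
        ant = next_gene(f"AN{p:02d}") if with_cofactors else None
        for i in range(interactions_per_pathway):
            tag = f"{p:02d}{chr(97 + i)}"
            lig = GeneComplex(name=f"L{tag}", subunits=(next_gene(f"L{tag}"),))
            if with_complexes and i % 2 == 1:
                subs = (next_gene(f"R{tag}"), next_gene(f"R{tag}x"))
                rec = GeneComplex(name="_".join(subs), subunits=subs)
            else:
                rec = GeneComplex(name=f"R{tag}", subunits=(next_gene(f"R{tag}"),))
            interactions.append(
                LRInteraction(
                    id=f"{pw}-I{i}",
                    ligand=lig,
                    receptor=rec,
                    pathway=pw,
                    agonists=(ago,) if ago else (),
                    antagonists=(ant,) if ant else (),
                    category="secreted",
                )
            )
    return LRDatabase(interactions=interactions)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draws via gamma-Poisson mixture."""
    lam = rng.gamma(shape=size_param, scale=np.maximum(mu, 1e-12) / size_param)
    return rng.poisson(lam)


def generate_dataset(cfg: SimConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Simulate a log-normalized dataset plus its ground-truth table.

    Counts are negative binomial around per-gene baseline means, scaled by
    log-normal per-sample-per-gene effects (SD ``sample_effect_sd``) and by
    the planted elevations/fold-changes, then library-normalized to the
    median cell total and log2(1+x)-transformed.  The truth table lists
    every planted differential route.
    """
    rng = np.random.default_rng(cfg.seed)
    db_genes = cfg.db.genes if cfg.db is not None else []
    n_bg = cfg.n_genes - len(db_genes)
    if n_bg < 0:
        raise ConfigError(
            f"n_genes={cfg.n_genes} smaller than the {len(db_genes)} database genes"
        )
    genes = db_genes + [f"BG{i:04d}" for i in range(n_bg)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    lig_genes: dict[str, list[str]] = {}
    rec_genes: dict[str, list[str]] = {}
    if cfg.db is not None:
        for it in cfg.db.interactions:
            lig_genes.setdefault(it.pathway, []).extend(it.ligand.subunits)
            rec_genes.setdefault(it.pathway, []).extend(it.receptor.subunits)
    for sig in cfg.planted_signals:
        if sig.pathway not in lig_genes:
            raise ConfigError(f"planted pathway {sig.pathway!r} not in database")
        if sig.condition not in cfg.condition_labels:
            raise ConfigError(f"unknown planted condition {sig.condition!r}")
        if sig.sender not in cfg.cell_types or sig.receiver not in cfg.cell_types:
            raise ConfigError("planted sender/receiver not among cell types")

    case_label, control_label = cfg.condition_labels
    samples = [f"{case_label}_{i + 1:02d}" for i in range(cfg.n_case)] + [
        f"{control_label}_{i + 1:02d}" for i in range(cfg.n_control)
    ]
    condition = {
        s: (case_label if s.startswith(case_label) else control_label) for s in samples
    }

    base_mu = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))

    # per-cell-type multipliers: database genes default to the low
    # background; planted routes switch them on in their sender/receiver
    db_gene_rows = [gene_pos[g] for g in db_genes]
    type_mult = {}
    for ct in cfg.cell_types:
        vec = np.ones(cfg.n_genes)
        vec[db_gene_rows] = cfg.db_background_level
        type_mult[ct] = vec
    # condition-dependent multipliers: (cell_type, condition) -> per-gene
    cond_mult: dict[tuple[str, str], np.ndarray] = {}
    for sig in cfg.planted_signals:
        for g in lig_genes[sig.pathway]:
            type_mult[sig.sender][gene_pos[g]] = max(
                type_mult[sig.sender][gene_pos[g]], sig.ligand_boost
            )
        for g in rec_genes[sig.pathway]:
            type_mult[sig.receiver][gene_pos[g]] = max(
                type_mult[sig.receiver][gene_pos[g]], sig.receptor_boost
            )
        key = (sig.sender, sig.condition)
        vec = cond_mult.setdefault(key, np.ones(cfg.n_genes))
        for g in lig_genes[sig.pathway]:
            vec[gene_pos[g]] *= sig.fold_change

    counts_blocks = []
    cell_ids: list[str] = []
    cell_type_labels: list[str] = []
    sample_labels: list[str] = []
    lo, hi = cfg.cells_per_sample_per_type
    for smp in samples:
        sample_effect = np.exp(
            rng.normal(-cfg.sample_effect_sd**2 / 2, cfg.sample_effect_sd, cfg.n_genes)
        )
        for ct in cfg.cell_types:
            n_cells = int(rng.integers(lo, hi + 1))
            mu = base_mu * sample_effect * type_mult[ct]
            extra = cond_mult.get((ct, condition[smp]))
            if extra is not None:
                mu = mu * extra
            block = _nb_counts(rng, np.broadcast_to(mu, (n_cells, cfg.n_genes)),
                               cfg.nb_dispersion)
            counts_blocks.append(block)
            start = len(cell_ids)
            cell_ids.extend(f"{smp}:{ct}:{start + j}" for j in range(n_cells))
            cell_type_labels.extend([ct] * n_cells)
            sample_labels.extend([smp] * n_cells)

    counts = np.vstack(counts_blocks).T.astype(float)  # genes x cells
    totals = counts.sum(axis=0)
    scale = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(totals > 0, counts / totals * scale, 0.0)
    matrix = np.log2(1.0 + normalized)

    truth = pd.DataFrame(
        [
            {
                "pathway": s.pathway,
                "sender": s.sender,
                "receiver": s.receiver,
                "condition": s.condition,
                "fold_change": s.fold_change,
                "differential": s.fold_change != 1.0,
                "ligand_genes": ",".join(sorted(set(lig_genes[s.pathway]))),
                "receptor_genes": ",".join(sorted(set(rec_genes[s.pathway]))),
            }
            for s in cfg.planted_signals
        ],
        columns=["pathway", "sender", "receiver", "condition", "fold_change",
                 "differential", "ligand_genes", "receptor_genes"],
    )
    ds = ExpressionDataset(
        matrix=matrix,
        genes=genes,
        cells=cell_ids,
        cell_type=np.array(cell_type_labels, object),
        sample=np.array(sample_labels, object),
        condition=condition,
    )
    return ds, truth


def default_study_config(seed: int = 0, db: LRDatabase | None = None,
                         n_pathways: int = 30, n_planted: int = 5) -> SimConfig:
    """The reference end-to-end configuration: ``n_planted`` differential
    pathways (ligand fold-change 2) among ``n_pathways``, routed through
    distinct sender/receiver types, 13 vs 10 samples, ~50 cells/type/sample.
    """
    if db is None:
        db = generate_toy_db(n_pathways, interactions_per_pathway=2, seed=seed)
    pathways = sorted(db.pathways)
    rng = np.random.default_rng(seed)
    chosen = [str(p) for p in rng.choice(pathways, size=n_planted, replace=False)]
    types = list(DEFAULT_CELL_TYPES)
    signals = []
    for i, pw in enumerate(chosen):
        sender = types[(2 * i) % len(types)]
        receiver = types[(2 * i + 1) % len(types)]
        signals.append(PlantedSignal(pathway=pw, sender=sender, receiver=receiver,
                                     fold_change=2.0, condition="case"))
    # remaining pathways stay active-but-null so they are detected in samples
    for j, pw in enumerate(p for p in pathways if p not in chosen):
        sender = types[(3 * j + 1) % len(types)]
        receiver = types[(3 * j + 2) % len(types)]
        signals.append(PlantedSignal(pathway=pw, sender=sender, receiver=receiver,
                                     fold_change=1.0, condition="case"))
    n_genes = len(db.genes) + 50
    return SimConfig(n_genes=n_genes, planted_signals=signals, db=db, seed=seed)


def generate_spatial(
    n_genes: int = 100,
    n_spots: int = 500,
    planted_pairs: list[tuple[str, str, float]] | None = None,
    layers: tuple[str, ...] = DEFAULT_LAYERS,
    mean: float = 2.0,
    sd: float = 0.5,
    seed: int = 0,
) -> SpatialDataset:
    """Spot x gene spatial fixture with planted correlated L-R pairs.

    ``planted_pairs`` holds (ligand gene, receptor gene, target rho) with
    rho in (-1, 1); those two genes are drawn from a bivariate normal on
    the log-expression scale while background genes are independent.
    Spots are assigned to layers uniformly at random.
    """
    planted_pairs = planted_pairs or []
    rng = np.random.default_rng(seed)
    genes = [f"SG{i:04d}" for i in range(n_genes)]
    pos = {g: i for i, g in enumerate(genes)}
    matrix = rng.normal(mean, sd, size=(n_genes, n_spots))
    for lg, rg, rho in planted_pairs:
        if not -1 < rho < 1:
            raise ConfigError(f"rho must lie in (-1, 1), got {rho}")
        if lg not in pos or rg not in pos:
            raise ConfigError("planted gene outside the spatial gene universe")
        cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
        draw = rng.multivariate_normal([mean, mean], cov, size=n_spots)
        matrix[pos[lg]] = draw[:, 0]
        matrix[pos[rg]] = draw[:, 1]
    matrix = np.clip(matrix, 0.0, None)
    layer = rng.choice(layers, size=n_spots)
    return SpatialDataset(matrix=matrix, genes=genes, layer=layer.astype(object))
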