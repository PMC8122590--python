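"""Weighted co-expression network and module detection, implemented in full.

The pipeline follows the WGCNA construction: FPKM values are normalized as
log10(FPKM + 1); Pearson correlation C across developmental stages; soft
adjacency a_ij = |c_ij|^beta (unsigned, default) or ((1 + c_ij)/2)^beta
(signed); topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu;

average-linkage hierarchical clustering on 1 - TOM; a static cut at
``cut_height`` × (maximum merge height); clusters below ``min_module_size``
relabeled grey; surviving modules colored by descending size in the
conventional color order (turquoise, blue, brown, ...).

Modules are then grouped by the developmental stage at which their mean
log-normalized profile peaks: pre-neurula stages → Group I, tailbud →
Group II, hatched larva onward → Group III.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform

#: Module colors in WGCNA's conventional size-rank order.
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
)

GREY = "grey"

#: Stage-index → developmental group: pre-neurula peaks are Group I,
#: tailbud Group II, hatched larva onward Group III (7-stage axis).
_GROUP_OF_STAGE_INDEX = ("I", "I", "I", "II", "III", "III", "III")


@dataclass
class ModuleDetectionParams:
    """Tunable parameters of module detection (defaults follow the published
    genome-wide run; scale ``min_module_size`` down for small matrices)."""

    soft_power: float = 12.0
    min_module_size: int = 300
    cut_height: float = 0.99
    deep_split: bool = False  # reserved; static cut only
    network_sign: str = "unsigned"

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must be in (0, 1]")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError("network_sign must be 'unsigned' or 'signed'")


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray | None = None
    tom: np.ndarray | None = None
    zero_variance_genes: set[str] = field(default_factory=set)


@dataclass
class ModulePartition:
    """gene → module color, module → developmental group, and the mean
    log-normalized stage profile per module."""

    labels: pd.Series
    groups: dict[str, str] = field(default_factory=dict)
    mean_profiles: pd.DataFrame | None = None
    merge_heights: np.ndarray | None = None
    linkage_matrix: np.ndarray | None = None

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def normalize_log10(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(FPKM + 1)."""
    if (matrix.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return np.log10(matrix + 1.0)


def call_expressed(matrix: pd.DataFrame, threshold: float, stage: str) -> set[str]:
    """Genes with FPKM strictly above ``threshold`` at ``stage``."""
    if stage not in matrix.columns:
        raise KeyError(f"unknown stage {stage!r}")
    col = matrix[stage]
    return set(col.index[col > threshold])


def collapse_replicates(matrix: pd.DataFrame, stage_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Average replicate columns ``<stage>_r<k>`` into one column per stage."""
    stage_of = {c: c.rsplit("_r", 1)[0] for c in matrix.columns}
    out = matrix.T.groupby(matrix.columns.map(stage_of), sort=False).mean().T
    if stage_order is not None:
        out = out.loc[:, list(stage_order)]
    return out


def percentage(count: int, universe_size: int) -> float:
    """100 × count / universe_size, to two decimals."""
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    return round(100.0 * count / universe_size, 2)


def expressed_proportion(
    matrix: pd.DataFrame, universe_size: int, threshold: float, stage: str
) -> float:
    """Percentage of a gene universe expressed (FPKM > threshold) at a stage."""
    return percentage(len(call_expressed(matrix, threshold, stage)), universe_size)


def correlation_matrix(matrix: pd.DataFrame, normalized: bool = False) -> CoexpressionNetwork:
    """Pearson correlation across stage columns of the log-normalized matrix.

    Zero-variance genes get correlation 0 to all others (flagged in
    ``zero_variance_genes``); the diagonal is 1 throughout.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 stage columns to correlate")
    values = matrix.values if normalized else normalize_log10(matrix).values
    sd = values.std(axis=1)
    flat = sd <= 1e-12 * np.maximum(1.0, np.abs(values).max(axis=1))
    corr = np.corrcoef(values)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return CoexpressionNetwork(
        gene_ids=list(matrix.index),
        correlation=corr,
        zero_variance_genes=set(matrix.index[flat]),
    )


def soft_adjacency(
    network: CoexpressionNetwork, params: ModuleDetectionParams
) -> CoexpressionNetwork:
    """Raise correlations to the soft power: a = |c|^beta (unsigned) or
    ((1 + c)/2)^beta (signed); unit diagonal."""
    c = network.correlation
    if params.network_sign == "unsigned":
        a = np.abs(c) ** params.soft_power
    else:
        a = ((1.0 + c) / 2.0) ** params.soft_power
    np.fill_diagonal(a, 1.0)
    network.adjacency = a
    return network


def compute_tom(network: CoexpressionNetwork) -> CoexpressionNetwork:
    """Topological overlap of the adjacency (vectorized; see module docstring
    for the elementwise formula)."""
    if network.adjacency is None:
        raise ValueError("adjacency not computed")
    a = network.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    network.tom = tom
    return network


def build_network(matrix: pd.DataFrame, params: ModuleDetectionParams) -> CoexpressionNetwork:
    """normalize → correlate → soft adjacency → TOM in one call."""
    return compute_tom(soft_adjacency(correlation_matrix(matrix), params))


def detect_modules(
    network: CoexpressionNetwork, params: ModuleDetectionParams
) -> ModulePartition:
    """Average-linkage clustering of 1 − TOM with a static height cut.

    The tree is cut at ``cut_height`` × (maximum merge height); clusters
    smaller than ``min_module_size`` are relabeled grey; surviving modules
    are colored by descending size (ties broken by earliest member index),
    deterministically.
    """
    if network.tom is None:
        raise ValueError("TOM not computed")
    n = len(network.gene_ids)
    if n < 2:
        raise ValueError("need at least 2 genes")
    dissim = 1.0 - network.tom
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    cut = params.cut_height * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")

    sizes: dict[int, int] = {}
    first_idx: dict[int, int] = {}
    for i, lab in enumerate(raw):
        sizes[lab] = sizes.get(lab, 0) + 1
        first_idx.setdefault(lab, i)
    surviving = [lab for lab in sizes if sizes[lab] >= params.min_module_size]
    surviving.sort(key=lambda lab: (-sizes[lab], first_idx[lab]))
    color_of = {
        lab: MODULE_COLORS[r] if r < len(MODULE_COLORS) else f"module{r + 1}"
        for r, lab in enumerate(surviving)
    }
    labels = pd.Series(
        [color_of.get(lab, GREY) for lab in raw], index=network.gene_ids, name="module"
    )
    return ModulePartition(labels=labels, merge_heights=z[:, 2].copy(), linkage_matrix=z)


def assign_groups(partition: ModulePartition, matrix: pd.DataFrame) -> ModulePartition:
    """Assign each non-grey module to developmental Group I/II/III by the
    argmax stage of its mean log-normalized profile (ties → earlier stage)."""
    log = normalize_log10(matrix)
    profiles = {}
    groups = {}
    for module in partition.labels.unique():
        genes = partition.genes_in(module)
        prof = log.loc[genes].mean(axis=0)
        profiles[module] = prof
        if module != GREY:
            peak_idx = int(np.argmax(prof.values))  # first max → earlier stage
            groups[module] = _GROUP_OF_STAGE_INDEX[peak_idx]
    partition.groups = groups
    partition.mean_profiles = pd.DataFrame(profiles).T
    return partition


def module_eigengene(matrix: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """First principal component of the standardized module submatrix
    (diagnostic only; group assignment uses the mean profile)."""
    sub = normalize_log10(matrix.loc[list(genes)]).values
    sd = sub.std(axis=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    if np.corrcoef(pc, z.mean(axis=0))[0, 1] < 0:
        pc = -pc  # orient along the mean profile
    return pd.Series(pc, index=matrix.columns)


def family_module_table(
    partition: ModulePartition, family_of: dict[str, str]
) -> pd.DataFrame:
    """Cross-tabulate partitioned genes into a families × modules count table
    (module columns in size-rank color order, grey last if present)."""
    missing = [g for g in partition.labels.index if g not in family_of]
    if missing:
        raise ValueError(f"genes without family assignment: {missing[:5]}...")
    df = pd.DataFrame(
        {
            "family": [family_of[g] for g in partition.labels.index],
            "module": partition.labels.values,
        }
    )
    table = pd.crosstab(df["family"], df["module"])
    order = [c for c in MODULE_COLORS if c in table.columns]
    order += [c for c in table.columns if c not in order and c != GREY]
    if GREY in table.columns:
        order.append(GREY)
    return table[order]


def order_for_heatmap(
    partition: ModulePartition, network: CoexpressionNetwork
) -> tuple[list[str], list[int]]:
    """Order genes by (developmental group, module size rank, within-module
    dendrogram order); returns the ordered gene list and the block start
    offsets (one block per module, grey last)."""
    genes = list(partition.labels.index)
    idx_of = {g: i for i, g in enumerate(network.gene_ids)}
    group_rank = {"I": 0, "II": 1, "III": 2}
    sizes = partition.module_sizes()

    def module_key(m: str):
        if m == GREY:
            return (9, 0, m)
        return (group_rank.get(partition.groups.get(m, "I"), 0), -sizes[m], m)

    modules = sorted(partition.labels.unique(), key=module_key)
    ordered: list[str] = []
    boundaries: list[int] = []
    dissim = 1.0 - network.tom if network.tom is not None else 1.0 - np.abs(network.correlation)
    for m in modules:
        boundaries.append(len(ordered))
        members = partition.genes_in(m)
        if len(members) > 2:
            rows = [idx_of[g] for g in members]
            sub = dissim[np.ix_(rows, rows)]
            z = linkage(squareform(sub, checks=False), method="average")
            leaf_order = dendrogram(z, no_plot=True)["leaves"]
            members = [members[i] for i in leaf_order]
        ordered.extend(members)
    return ordered, boundaries


def mean_block_correlations(
    ordered: Sequence[str], boundaries: Sequence[int], network: CoexpressionNetwork
) -> tuple[float, float]:
    """Mean within-block vs between-block correlation for a heatmap ordering."""
    idx_of = {g: i for i, g in enumerate(network.gene_ids)}
    block_of = np.zeros(len(ordered), dtype=int)
    for b, start in enumerate(boundaries):
        end = boundaries[b + 1] if b + 1 < len(boundaries) else len(ordered)
        block_of[start:end] = b
    rows = np.array([idx_of[g] for g in ordered])
    c = network.correlation[np.ix_(rows, rows)]
    same = np.equal.outer(block_of, block_of)
    off_diag = ~np.eye(len(ordered), dtype=bool)
    within = c[same & off_diag]
    between = c[~same]
    return float(within.mean()), float(between.mean()) if between.size else float("nan")
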