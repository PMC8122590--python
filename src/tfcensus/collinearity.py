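"""Hox-cluster positional analysis: chromosomal distribution, expression
onset, subcluster temporal collinearity (STC), and cross-species cluster
arrangement comparison.

STC means that within a genomically contiguous run of cluster genes the
order of expression onsets matches genomic order exactly (forward) or
exactly reverses it (reverse). Onset is formalized as the earliest
developmental stage at which FPKM exceeds a threshold (default 10, the
same cutoff used for "expressed" calls). Rank agreement uses Kendall
tau-b, which is tie-corrected — onset stages are heavily tied ordinal data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import kendalltau

from .io_formats import STAGES, GeneLocus


@dataclass(frozen=True)
class ClusterGene:
    """One gene of a genomic cluster (e.g. Hox), with its paralog-group
    assignment (1–13, or None when unclassified) taken as given input."""

    gene_id: str
    paralog_group: int | None
    locus: GeneLocus
    onset_stage: str | None = None

    def __post_init__(self) -> None:
        if self.paralog_group is not None and not (1 <= self.paralog_group <= 13):
            raise ValueError(f"paralog group out of range for {self.gene_id}")


@dataclass
class ChromosomeCensus:
    counts: dict[str, int]
    single_chromosome: bool


@dataclass
class CollinearityResult:
    """A maximal collinear window: the genes in genomic order, their Kendall
    tau against onset order, and the orientation (+1 → forward, −1 → reverse)."""

    subcluster: list[ClusterGene]
    tau: float
    orientation: str  # forward | reverse | none

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.subcluster]


def chromosome_census(loci: Sequence[GeneLocus]) -> ChromosomeCensus:
    """Gene counts per chromosome, plus whether all genes share one."""
    counts = Counter(loc.chromosome for loc in loci)
    return ChromosomeCensus(dict(counts), single_chromosome=len(counts) == 1)


def onset_stage(
    gene_id: str, matrix: pd.DataFrame, threshold: float = 10.0
) -> str | None:
    """Earliest stage (canonical order) with FPKM strictly above threshold;
    ``None`` when the gene never exceeds it."""
    if gene_id not in matrix.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    row = matrix.loc[gene_id]
    for stage in [s for s in STAGES if s in matrix.columns]:
        if row[stage] > threshold:
            return stage
    return None


def stage_rank(stage: str) -> int:
    return STAGES.index(stage)


def collinearity_tau(
    genomic_ranks: Sequence[int], onset_ranks: Sequence[int]
) -> float:
    """Kendall tau-b between genomic rank and onset-stage rank.

    Fully tied onset sequences have undefined tau-b; 0 is returned (no
    collinearity signal either way).
    """
    if len(genomic_ranks) < 3:
        raise ValueError("need at least 3 genes")
    if len(genomic_ranks) != len(onset_ranks):
        raise ValueError("rank lists differ in length")
    tau = kendalltau(genomic_ranks, onset_ranks, variant="b").statistic
    if pd.isna(tau):
        return 0.0
    if abs(abs(tau) - 1.0) < 1e-12:  # snap float noise at perfect collinearity
        return 1.0 if tau > 0 else -1.0
    return float(tau)


def find_collinear_subclusters(
    cluster: Sequence[ClusterGene],
    min_len: int = 3,
    perfect_only: bool = True,
    tau_threshold: float = 1.0,
) -> list[CollinearityResult]:
    """All maximal genomically contiguous windows (length >= min_len) whose
    members all have onsets and whose onset order is perfectly collinear
    with genomic order (|tau| = 1 when ``perfect_only``; |tau| >=
    ``tau_threshold`` otherwise). Genes without an onset break windows; a
    window is reported only if no extension of it also qualifies.
    """
    thr = 1.0 if perfect_only else tau_threshold
    qualifying: list[tuple[int, int]] = []  # [start, end) in cluster coords
    n = len(cluster)
    # segments of consecutive genes that all have onsets
    seg_start = 0
    segments = []
    for i in range(n + 1):
        if i == n or cluster[i].onset_stage is None:
            if i - seg_start >= min_len:
                segments.append((seg_start, i))
            seg_start = i + 1
    for s, e in segments:
        for length in range(min_len, e - s + 1):
            for start in range(s, e - length + 1):
                window = cluster[start:start + length]
                tau = collinearity_tau(
                    list(range(length)),
                    [stage_rank(g.onset_stage) for g in window],  # type: ignore[arg-type]
                )
                if abs(tau) >= thr - 1e-12:
                    qualifying.append((start, start + length))
    maximal = [
        (s, e)
        for s, e in qualifying
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in qualifying)
    ]
    results = []
    for s, e in sorted(maximal):
        window = list(cluster[s:e])
        tau = collinearity_tau(
            list(range(e - s)), [stage_rank(g.onset_stage) for g in window]  # type: ignore[arg-type]
        )
        orientation = "forward" if tau > 0 else "reverse" if tau < 0 else "none"
        results.append(CollinearityResult(window, tau, orientation))
    return results


def compare_arrangements(
    cluster_a: Sequence[ClusterGene], cluster_b: Sequence[ClusterGene]
) -> tuple[set[int], bool, bool]:
    """Compare two clusters given in genomic order.

    Returns (shared paralog groups, same_order, same_linkage): same_order is
    true when the shared PGs appear in the same relative order in both
    clusters or in exact reversal; same_linkage is true when both clusters
    lie each on a single chromosome.
    """
    pgs_a = [g.paralog_group for g in cluster_a if g.paralog_group is not None]
    pgs_b = [g.paralog_group for g in cluster_b if g.paralog_group is not None]
    shared = set(pgs_a) & set(pgs_b)
    order_a = [pg for pg in pgs_a if pg in shared]
    order_b = [pg for pg in pgs_b if pg in shared]
    same_order = order_a == order_b or order_a == order_b[::-1]
    single_a = chromosome_census([g.locus for g in cluster_a]).single_chromosome
    single_b = chromosome_census([g.locus for g in cluster_b]).single_chromosome
    return shared, same_order, single_a and single_b
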