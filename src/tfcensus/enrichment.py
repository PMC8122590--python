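"""Term enrichment of a TF subset against a TF background, and the
comparative-Ct arithmetic for qPCR validation.

Enrichment is the one-sided hypergeometric upper tail — for a target set of
size n drawn from a background of size N in which K genes carry a term,
the p-value of observing k or more annotated target genes — with
Benjamini–Hochberg adjustment across all tested terms (terms annotated in
at least one background gene). Annotations are used exactly as supplied;
no ontology-graph propagation is performed.

Relative qPCR expression uses 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference)
per condition and ΔΔCt = ΔCt(treated) − ΔCt(control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # target genes with term
    K: int  # background genes with term
    n: int  # target size
    N: int  # background size
    p_value: float
    q_value: float
    fold: float


@dataclass(frozen=True)
class QpcrMeasurement:
    gene: str
    condition: str
    ct_target: float
    ct_reference: float


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich(
    target: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    top_n: int = 20,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term with background support,
    BH-adjusted over all tested terms, ranked by p (ties by term id) and
    truncated to ``top_n``."""
    target_set = set(target)
    background_set = set(background)
    if not target_set <= background_set:
        raise ValueError("target must be a subset of the background")
    n, N = len(target_set), len(background_set)
    genes_of_term: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene in background_set:
            for t in terms:
                genes_of_term.setdefault(t, set()).add(gene)
    terms = sorted(genes_of_term)  # only terms with K >= 1 are tested
    if not terms:
        return []
    rows = []
    for t in terms:
        K = len(genes_of_term[t])
        k = len(genes_of_term[t] & target_set)
        p = hypergeometric_upper(k, K, n, N)
        fold = (k / n) / (K / N) if n and k else 0.0
        rows.append((t, k, K, p, fold))
    _, q_values, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(t, k, K, n, N, p, float(q), fold)
        for (t, k, K, p, fold), q in zip(rows, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results[:top_n]


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH step-up q-values in the input order (thin statsmodels wrapper)."""
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def delta_delta_ct(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression 2^−ΔΔCt of treated vs control."""
    if treated.gene != control.gene:
        raise ValueError("measurements must share the gene")
    d_treated = treated.ct_target - treated.ct_reference
    d_control = control.ct_target - control.ct_reference
    return float(2.0 ** (-(d_treated - d_control)))
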