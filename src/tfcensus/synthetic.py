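"""Seeded generators for every input the pipeline consumes, with known
ground truth, so every stage is testable without the deposited genome and
transcriptome data.

All generators are pure functions of their arguments including the seed:
the same call produces byte-identical files and identical truth tables.

What is emulated (and what is not): domain tables carry planted DBD
architectures per family — including compound BTB + zf-C2H2 proteins and
sub-threshold decoy hits kept at least 10× above their family threshold so
boundary-inclusivity choices cannot flip a decoy — over proteomes with 1–4
isoforms per gene of which only the longest carries the full hit set.
Expression matrices carry stage-peaked modules over the seven developmental
stages (three replicate libraries per stage) with a prescribed expected
within-module correlation, simulated on the log10 scale and transformed to
FPKM by 10^x − 1. Protein sequences are random residues of the stated
lengths; no read-level RNA-seq realism is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .classifier import FamilyRuleSet, default_rules
from .io_formats import STAGES, DomainHit, GeneLocus, ProteinRecord

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Default family mix, loosely shaped like an ascidian TF complement.
DEFAULT_FAMILY_MIX: dict[str, float] = {
    "zf-C2H2": 0.28,
    "Homeodomain": 0.14,
    "bHLH": 0.08,
    "Forkhead box": 0.06,
    "HMG_box": 0.05,
    "bZIP_1": 0.05,
    "Ets": 0.04,
    "T-box": 0.04,
    "Myb_DNA-binding": 0.04,
    "THAP": 0.04,
    "zf-BED": 0.03,
    "Hormone_receptor": 0.03,
    "PAX": 0.03,
    "CSD": 0.03,
    "TIG": 0.03,
    "GATA": 0.03,
}


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run, keyed by gene id."""

    seed: int
    planted_family_per_gene: dict[str, str] = field(default_factory=dict)
    planted_subtypes: dict[str, str] = field(default_factory=dict)
    planted_module_per_gene: dict[str, str] = field(default_factory=dict)
    planted_onsets: dict[str, str] = field(default_factory=dict)
    planted_enriched_terms: set[str] = field(default_factory=set)


@dataclass
class DomainSimulation:
    hits: list[DomainHit]
    proteins: list[ProteinRecord]
    sequences: dict[str, str]
    truth: SimulationTruth


def _mix_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes to the mix proportions."""
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"family proportions sum to {total}, not 1")
    raw = {f: n * p for f, p in mix.items()}
    counts = {f: int(v) for f, v in raw.items()}
    short = n - sum(counts.values())
    for f in sorted(raw, key=lambda f: (counts[f] - raw[f], f))[:short]:
        counts[f] += 1
    return counts


def _family_accession(rules: FamilyRuleSet, family: str) -> str:
    for acc, rule in rules.rules.items():
        if rule.family == family:
            return acc
    raise ValueError(f"family {family!r} not in rule set")


def _planted_evalue(rng: np.random.Generator, threshold: float) -> float:
    """Log-uniform, 1–10 decades below the family threshold."""
    return threshold * 10.0 ** (-rng.uniform(1.0, 10.0))


def _decoy_evalue(rng: np.random.Generator, threshold: float) -> float:
    """Log-uniform, 1–4 decades above the threshold (>= 10x margin)."""
    return threshold * 10.0 ** (rng.uniform(1.0, 4.0))


def simulate_domtblout(
    n_tf: int,
    family_mix: dict[str, float] | None = None,
    n_decoys: int = 0,
    n_compound: int = 0,
    seed: int = 0,
    rules: FamilyRuleSet | None = None,
    out_dir: str | Path | None = None,
) -> DomainSimulation:
    """Simulate a domain-annotation table plus proteome with planted TFs.

    ``n_compound`` of the ``n_tf`` TF genes are compound BTB + zf-C2H2
    (ZBTB) genes; the rest draw families from ``family_mix``. Decoy genes
    receive only hits at least 10× above their family threshold. Each gene
    gets 1–4 isoforms; only the longest isoform carries the hits.

    When ``out_dir`` is given, writes ``domains.domtbl``, ``proteome.fasta``
    and ``truth.tsv`` there.
    """
    if n_compound > n_tf:
        raise ValueError("n_compound cannot exceed n_tf")
    rules = rules or default_rules()
    mix = family_mix or DEFAULT_FAMILY_MIX
    unknown = [f for f in mix if f not in set(rules.families)]
    if unknown:
        raise ValueError(f"families not in rule set: {unknown}")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    hits: list[DomainHit] = []
    proteins: list[ProteinRecord] = []
    sequences: dict[str, str] = {}

    fam_counts = _mix_counts(n_tf - n_compound, mix)
    families: list[str] = []
    for fam in sorted(fam_counts):
        families.extend([fam] * fam_counts[fam])
    rng.shuffle(families)
    families = ["__ZBTB__"] * n_compound + families

    def add_gene(gene_id: str, hit_specs: list[tuple[str, float]]) -> None:
        """Register isoforms for a gene; the longest carries the hits."""
        n_iso = int(rng.integers(1, 5))
        lengths = sorted(set(rng.integers(150, 900, size=n_iso).tolist()))
        while len(lengths) < n_iso:
            lengths.append(lengths[-1] + int(rng.integers(1, 50)))
        longest = max(lengths)
        for k, length in enumerate(sorted(lengths)):
            pid = f"{gene_id}.p{k + 1}"
            proteins.append(ProteinRecord(pid, gene_id, int(length)))
            sequences[pid] = "".join(
                rng.choice(list(_RESIDUES), size=int(length)).tolist()
            )
            if length == longest:
                for acc, evalue in hit_specs:
                    rule = rules.rules[acc]
                    start = int(rng.integers(0, max(1, length - 60)))
                    hits.append(
                        DomainHit(
                            protein_id=pid,
                            pfam_accession=acc,
                            domain_name=rule.family.replace(" ", "_"),
                            full_seq_evalue=evalue,
                            ind_domain_evalue=evalue,
                            bit_score=float(np.round(rng.uniform(30, 300), 1)),
                            env_start=start,
                            env_end=start + 50,
                        )
                    )

    for i, fam in enumerate(families):
        gene_id = f"g{i:04d}"
        if fam == "__ZBTB__":
            specs = [
                ("PF00651", _planted_evalue(rng, rules.rules["PF00651"].evalue_threshold)),
                ("PF00096", _planted_evalue(rng, rules.rules["PF00096"].evalue_threshold)),
            ]
            truth.planted_family_per_gene[gene_id] = "zf-C2H2"
            truth.planted_subtypes[gene_id] = "ZBTB"
        else:
            acc = _family_accession(rules, fam)
            specs = [(acc, _planted_evalue(rng, rules.rules[acc].evalue_threshold))]
            truth.planted_family_per_gene[gene_id] = fam
        add_gene(gene_id, specs)

    decoy_accs = sorted(rules.rules)
    for i in range(n_decoys):
        gene_id = f"d{i:04d}"
        n_hits = int(rng.integers(1, 3))
        specs = []
        for _ in range(n_hits):
            acc = decoy_accs[int(rng.integers(0, len(decoy_accs)))]
            specs.append((acc, _decoy_evalue(rng, rules.rules[acc].evalue_threshold)))
        add_gene(gene_id, specs)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_domtblout(hits, out / "domains.domtbl")
        io_formats.write_protein_fasta(proteins, sequences, out / "proteome.fasta")
        rows = [
            {"gene_id": g, "family": f,
             "subtype": truth.planted_subtypes.get(g, "")}
            for g, f in sorted(truth.planted_family_per_gene.items())
        ]
        pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    return DomainSimulation(hits, proteins, sequences, truth)


@dataclass
class ExpressionSimulation:
    matrix: pd.DataFrame  # genes x replicate columns (FPKM)
    truth: SimulationTruth


def _bump_profile(peak_idx: int, amplitude: float = 2.0, width: float = 1.0) -> np.ndarray:
    s = np.arange(len(STAGES), dtype=float)
    return amplitude * np.exp(-((s - peak_idx) ** 2) / (2.0 * width**2))


def simulate_expression(
    n_genes: int,
    module_spec: list[tuple[int, str, float]],
    noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> ExpressionSimulation:
    """Simulate a stage-peaked FPKM matrix with planted module structure.

    ``module_spec`` entries are (size, peak_stage, within_correlation).
    Genes of a module share a Gaussian-bump latent profile (on the log10
    scale) centred on the peak stage; independent per-gene noise is scaled
    so two module genes have the stated expected Pearson correlation across
    stages. Remaining genes are unstructured background. ``noise_sd`` is
    the replicate-level library noise. FPKM = 10^x − 1, clipped at 0.

    Truth labels are ``M1, M2, ...`` in spec order; background is ``none``.
    """
    sizes = sum(s for s, _, _ in module_spec)
    if sizes > n_genes:
        raise ValueError("module sizes exceed n_genes")
    for _, peak, _ in module_spec:
        if peak not in STAGES:
            raise ValueError(f"unknown peak stage {peak!r}")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    profiles = np.zeros((n_genes, len(STAGES)))
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    row = 0
    for m, (size, peak, rho) in enumerate(module_spec, start=1):
        if not (0 < rho <= 1):
            raise ValueError("within-module correlation must be in (0, 1]")
        bump = _bump_profile(STAGES.index(peak))
        bump_var = float(np.var(bump))
        sigma = math.sqrt(bump_var * (1.0 - rho) / rho) if rho < 1 else 0.0
        for _ in range(size):
            profiles[row] = bump + sigma * rng.standard_normal(len(STAGES))
            truth.planted_module_per_gene[gene_ids[row]] = f"M{m}"
            row += 1
    for i in range(row, n_genes):
        base = rng.uniform(0.0, 0.5)
        profiles[i] = base + 0.3 * rng.standard_normal(len(STAGES))
        truth.planted_module_per_gene[gene_ids[i]] = "none"

    cols, data = [], []
    for s, stage in enumerate(STAGES):
        for r in range(1, replicates + 1):
            cols.append(f"{stage}_r{r}")
            x = profiles[:, s] + noise_sd * rng.standard_normal(n_genes)
            data.append(np.clip(10.0**x - 1.0, 0.0, None))
    matrix = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    if out_path is not None:
        io_formats.write_expression_table(matrix, out_path)
    return ExpressionSimulation(matrix, truth)


@dataclass
class HoxSimulation:
    loci: list[GeneLocus]
    paralog_groups: dict[str, int]
    matrix: pd.DataFrame
    truth: SimulationTruth


def _has_perfect_window(ranks: list[int], min_len: int = 3) -> bool:
    n = len(ranks)
    for length in range(min_len, n + 1):
        for start in range(n - length + 1):
            w = ranks[start:start + length]
            if all(a < b for a, b in zip(w, w[1:])) or all(
                a > b for a, b in zip(w, w[1:])
            ):
                return True
    return False


def simulate_hox_cluster(
    n_genes: int,
    orientation: str = "forward",
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> HoxSimulation:
    """Simulate a single-chromosome Hox-like cluster with planted onsets.

    ``forward``/``reverse`` place strictly increasing/decreasing onset
    stages along genomic order (needs n_genes <= number of stages);
    ``shuffled`` rejection-samples onsets with no strictly monotone window
    of length 3 (when feasible). Expression is 0 before the onset stage and
    well above the onset threshold from it onward.
    """
    if orientation not in ("forward", "reverse", "shuffled"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed)
    gene_ids = [f"Hox{i + 1}" for i in range(n_genes)]
    loci = [
        GeneLocus(g, "chr1", 10_000 + 5_000 * i, 12_000 + 5_000 * i, "+")
        for i, g in enumerate(gene_ids)
    ]
    pgs = {g: i + 1 for i, g in enumerate(gene_ids)}
    n_stages = len(STAGES)
    if orientation in ("forward", "reverse"):
        if n_genes > n_stages:
            raise ValueError("strict collinearity needs n_genes <= stage count")
        ranks = sorted(rng.choice(n_stages, size=n_genes, replace=False).tolist())
        if orientation == "reverse":
            ranks = ranks[::-1]
    else:
        for _ in range(10_000):
            ranks = rng.integers(0, n_stages, size=n_genes).tolist()
            if not _has_perfect_window(ranks):
                break
        else:  # pragma: no cover - feasible for n_genes >= 3
            raise RuntimeError("could not sample a non-collinear arrangement")
    values = np.zeros((n_genes, n_stages))
    for i, rank in enumerate(ranks):
        values[i, rank:] = 100.0
        truth.planted_onsets[gene_ids[i]] = STAGES[rank]
    matrix = pd.DataFrame(values, index=gene_ids, columns=list(STAGES))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_bed(loci, out / "hox.bed")
        pd.DataFrame(
            {"gene_id": gene_ids, "paralog_group": [pgs[g] for g in gene_ids]}
        ).to_csv(out / "pg.tsv", sep="\t", index=False)
        io_formats.write_expression_table(matrix, out / "hox_expr.tsv")
    return HoxSimulation(loci, pgs, matrix, truth)


@dataclass
class AnnotationSimulation:
    annotations: dict[str, set[str]]
    target: set[str]
    background: set[str]
    truth: SimulationTruth


def simulate_annotation(
    n_genes: int,
    n_terms: int,
    enriched_term_fold: float = 5.0,
    target_fraction: float = 0.3,
    base_rate: float = 0.1,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> AnnotationSimulation:
    """Simulate gene→term annotations with one planted enriched term.

    The planted term (``T000``) annotates target genes at
    ``enriched_term_fold`` × ``base_rate`` and non-target genes at
    ``base_rate``; decoy terms annotate all genes at ``base_rate``
    independently of target membership.
    """
    p_enriched = enriched_term_fold * base_rate
    if p_enriched > 1.0:
        raise ValueError("enriched_term_fold infeasible for this base rate")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(seed=seed, planted_enriched_terms={"T000"})
    genes = [f"g{i:04d}" for i in range(n_genes)]
    n_target = int(round(target_fraction * n_genes))
    target = set(rng.choice(genes, size=n_target, replace=False).tolist())
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        p = p_enriched if g in target else base_rate
        if rng.random() < p:
            annotations[g].add("T000")
        for t in range(1, n_terms):
            if rng.random() < base_rate:
                annotations[g].add(f"T{t:03d}")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "annotations.tsv", "w") as fh:
            fh.write("gene_id\tterm_id\n")
            for g in genes:
                for t in sorted(annotations[g]):
                    fh.write(f"{g}\t{t}\n")
        with open(out / "target.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(target))
    return AnnotationSimulation(annotations, target, set(genes), truth)
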