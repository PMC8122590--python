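"""TF identification and family classification from Pfam DBD annotation.

A gene is called a transcription factor when, after isoform deduplication,
its protein carries at least one DNA-binding-domain hit passing the
per-family e-value threshold (default 1e-4, with the conventional
family-specific overrides: bHLH 1e-2; HMG_box, Homeodomain, zf-BED and
zf-C2H2 1e-3; zf-CCCH 1e-20). Family assignment is deterministic:

1. compound-domain rules first — a gene with passing hits from every
   required family of a compound rule is assigned the rule's host family
   and tagged with the subtype (shipped default: BTB + zf-C2H2 → ZBTB,
   hosted in zf-C2H2);
2. otherwise the family of the passing hit with the smallest e-value,
   ties broken by larger bit score, then alphabetical family name.

All families that contributed at least one passing hit are retained in
``candidate_families`` as an audit trail.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    DomainHit,
    ProteinRecord,
    ValidationError,
    _data_path,
    select_longest_isoform,
    strip_accession_version,
)


@dataclass(frozen=True)
class FamilyRule:
    family: str
    superfamily: str | None
    evalue_threshold: float


@dataclass(frozen=True)
class CompoundRule:
    """A domain-architecture subtype: all ``required_families`` must have a
    passing hit on the gene; the assignment is hosted in ``host_family``."""

    subtype_name: str
    required_families: frozenset[str]
    host_family: str


DEFAULT_COMPOUND_RULES: tuple[CompoundRule, ...] = (
    CompoundRule("ZBTB", frozenset({"BTB", "zf-C2H2"}), "zf-C2H2"),
)


@dataclass
class FamilyRuleSet:
    """Mapping from Pfam accession to TF family plus per-family thresholds."""

    rules: dict[str, FamilyRule]
    default_threshold: float = 1e-4
    compound_rules: tuple[CompoundRule, ...] = DEFAULT_COMPOUND_RULES

    def __post_init__(self) -> None:
        if self.default_threshold <= 0:
            raise ValidationError("default threshold must be positive")
        for acc, rule in self.rules.items():
            if rule.evalue_threshold <= 0:
                raise ValidationError(f"non-positive threshold for {acc}")

    @property
    def families(self) -> list[str]:
        seen: list[str] = []
        for rule in self.rules.values():
            if rule.family not in seen:
                seen.append(rule.family)
        return seen

    @property
    def superfamily_of(self) -> dict[str, str | None]:
        return {r.family: r.superfamily for r in self.rules.values()}

    def threshold_for(self, accession: str) -> float | None:
        rule = self.rules.get(strip_accession_version(accession))
        return rule.evalue_threshold if rule else None

    def family_for(self, accession: str) -> str | None:
        rule = self.rules.get(strip_accession_version(accession))
        return rule.family if rule else None

    def with_threshold(self, family: str, threshold: float) -> "FamilyRuleSet":
        """A copy with one family's threshold replaced (all its accessions)."""
        new = {
            acc: (FamilyRule(r.family, r.superfamily, threshold)
                  if r.family == family else r)
            for acc, r in self.rules.items()
        }
        return FamilyRuleSet(new, self.default_threshold, self.compound_rules)


def read_rules(path: str | Path,
               compound_rules: Sequence[CompoundRule] = DEFAULT_COMPOUND_RULES,
               default_threshold: float = 1e-4) -> FamilyRuleSet:
    """Read a rules TSV (pfam_accession, family, superfamily, evalue_threshold)."""
    rules: dict[str, FamilyRule] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            acc = strip_accession_version(row["pfam_accession"])
            if acc in rules:
                raise ValidationError(f"accession {acc} mapped twice")
            thr = float(row["evalue_threshold"]) if row.get("evalue_threshold") else default_threshold
            rules[acc] = FamilyRule(row["family"], row.get("superfamily") or None, thr)
    return FamilyRuleSet(rules, default_threshold, tuple(compound_rules))


def default_rules() -> FamilyRuleSet:
    """The shipped 85-accession DBD rule set."""
    return read_rules(_data_path("dbd_rules.tsv"))


@dataclass
class TFAssignment:
    """One classified TF gene with its audit trail."""

    gene_id: str
    family: str
    superfamily: str | None
    subtype: str | None
    passing_hits: list[DomainHit]
    candidate_families: set[str] = field(default_factory=set)

    @property
    def best_evalue(self) -> float:
        return min(h.full_seq_evalue for h in self.passing_hits)


def apply_thresholds(
    hits: Iterable[DomainHit], rules: FamilyRuleSet, use_full_seq: bool = True
) -> list[DomainHit]:
    """Keep hits whose e-value passes the threshold of the family their
    accession maps to; hits on accessions outside the rule set are dropped
    silently (non-DBD domains). The boundary is inclusive (e <= t passes).

    ``use_full_seq`` selects the full-sequence e-value (default, matching the
    screening style of the TF databases the thresholds come from) versus the
    per-domain independent e-value.
    """
    kept = []
    for h in hits:
        thr = rules.threshold_for(h.pfam_accession)
        if thr is None:
            continue
        ev = h.full_seq_evalue if use_full_seq else h.ind_domain_evalue
        if ev <= thr:
            kept.append(h)
    return kept


def assign_family(
    gene_id: str,
    hits: Iterable[DomainHit],
    rules: FamilyRuleSet,
    protein_to_gene: Mapping[str, str] | None = None,
    use_full_seq: bool = True,
) -> TFAssignment | None:
    """Classify one gene from its domain hits; ``None`` when no hit passes.

    ``protein_to_gene``, when given, is used to verify that all hits belong
    to the stated gene (a contract violation otherwise).
    """
    hits = list(hits)
    if protein_to_gene is not None:
        genes = {protein_to_gene.get(h.protein_id, h.protein_id) for h in hits}
        if genes - {gene_id}:
            raise ValidationError(
                f"hits for gene {gene_id} span gene ids {sorted(genes)}"
            )
    passing = apply_thresholds(hits, rules, use_full_seq=use_full_seq)
    if not passing:
        return None
    candidates = {rules.family_for(h.pfam_accession) for h in passing}
    candidates.discard(None)

    family: str | None = None
    subtype: str | None = None
    for rule in rules.compound_rules:
        if rule.required_families <= candidates:
            family, subtype = rule.host_family, rule.subtype_name
            break
    if family is None:
        def sort_key(h: DomainHit):
            ev = h.full_seq_evalue if use_full_seq else h.ind_domain_evalue
            return (ev, -h.bit_score, rules.family_for(h.pfam_accession))

        family = rules.family_for(min(passing, key=sort_key).pfam_accession)
    return TFAssignment(
        gene_id=gene_id,
        family=family,
        superfamily=rules.superfamily_of.get(family),
        subtype=subtype,
        passing_hits=passing,
        candidate_families=set(candidates),  # type: ignore[arg-type]
    )


def classify_proteome(
    hits: Iterable[DomainHit],
    proteins: Iterable[ProteinRecord],
    rules: FamilyRuleSet,
    use_full_seq: bool = True,
) -> list[TFAssignment]:
    """End-to-end classification of one proteome.

    Composes longest-isoform selection, threshold filtering and per-gene
    family assignment; returns one assignment per TF gene, sorted by gene id.
    """
    kept = select_longest_isoform(proteins)
    kept_proteins = {p.protein_id for p in kept}
    gene_of = {p.protein_id: p.gene_id for p in kept}
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.protein_id in kept_proteins:
            by_gene.setdefault(gene_of[h.protein_id], []).append(h)
    out = []
    for gene_id in sorted(by_gene):
        a = assign_family(gene_id, by_gene[gene_id], rules, use_full_seq=use_full_seq)
        if a is not None:
            out.append(a)
    return out


def count_subtype(assignments: Iterable[TFAssignment], subtype_name: str) -> int:
    """Number of assignments carrying a given compound-domain subtype."""
    return sum(1 for a in assignments if a.subtype == subtype_name)
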