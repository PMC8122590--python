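"""Readers and writers for the external formats the pipeline consumes.

Supported formats:

* HMMER 3 per-domain tabular output ("domtblout", as written by ``hmmscan
  --domtblout``) — one :class:`DomainHit` per non-comment line.
* Protein FASTA with a ``gene=`` tag in the description, carrying the
  protein→gene mapping used for isoform deduplication.
* BED (6-column) gene loci.
* Gene-by-stage expression tables as TSV (FPKM), optionally with replicate
  columns ``<stage>_r1 .. <stage>_rK`` that are collapsed by mean.
* The packaged census fixtures mirroring the published family-count tables.

All genomic intervals are held 0-based half-open (BED convention); domtblout
envelope coordinates, which are 1-based inclusive on the protein, are
converted on read.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .census import FamilyCountMatrix

#: Canonical developmental-stage order: 2-cell to 8-cell embryos, gastrula,
#: neurula, tailbud, hatched swimming larva, tail-regressed larva,
#: metamorphic juvenile.
STAGES: tuple[str, ...] = ("2-8cells", "gast", "neu", "tb", "hsl", "trl", "mj")

#: Column count of the fixed (non-description) part of a domtblout line.
_DOMTBL_MIN_COLS = 22


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class ValidationError(ValueError):
    """Parsed content violates a documented invariant."""


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-domain match on one protein.

    ``env_start``/``env_end`` are the envelope coordinates on the protein,
    stored 0-based half-open.
    """

    protein_id: str
    pfam_accession: str
    domain_name: str
    full_seq_evalue: float
    ind_domain_evalue: float
    bit_score: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.full_seq_evalue < 0 or self.ind_domain_evalue < 0:
            raise ValidationError(f"negative e-value on hit {self.protein_id}")
        if self.env_start < 0 or self.env_end <= self.env_start:
            raise ValidationError(
                f"bad envelope [{self.env_start}, {self.env_end}) on {self.protein_id}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein isoform and the gene it belongs to."""

    protein_id: str
    gene_id: str
    sequence_length: int

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValidationError(f"non-positive length for {self.protein_id}")


@dataclass(frozen=True)
class GeneLocus:
    """A gene interval, 0-based half-open (BED convention)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad interval for {self.gene_id}")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")


def strip_accession_version(accession: str) -> str:
    """``PF00096.23`` → ``PF00096``; accessions without a version pass through."""
    return accession.split(".", 1)[0]


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER 3 per-domain tabular output into :class:`DomainHit` records.

    Comment lines (leading ``#``) are skipped; input order is preserved;
    Pfam accession version suffixes are stripped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(fields)}"
                )
            try:
                env_from = int(fields[19])
                env_to = int(fields[20])
                hits.append(
                    DomainHit(
                        protein_id=fields[3],
                        pfam_accession=strip_accession_version(fields[1]),
                        domain_name=fields[0],
                        full_seq_evalue=float(fields[6]),
                        ind_domain_evalue=float(fields[12]),
                        bit_score=float(fields[7]),
                        env_start=env_from - 1,  # 1-based inclusive -> 0-based half-open
                        env_end=env_to,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the hmmscan per-domain tabular layout (inverse of
    :func:`parse_domtblout`; unknown hmmscan columns are filled neutrally)."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  acc\n")
        fh.write("#" + "-" * 120 + "\n")
        for h in hits:
            env_from = h.env_start + 1
            env_to = h.env_end
            fh.write(
                f"{h.domain_name} {h.pfam_accession}.1 {env_to - env_from + 1} "
                f"{h.protein_id} - 500 {h.full_seq_evalue:.17g} {h.bit_score:.17g} 0.0 "
                f"1 1 {h.ind_domain_evalue:.17g} {h.ind_domain_evalue:.17g} "
                f"{h.bit_score:.17g} 0.0 1 {env_to - env_from + 1} "
                f"{env_from} {env_to} {env_from} {env_to} 0.95 -\n"
            )


def select_longest_isoform(proteins: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Keep one protein per gene: maximal ``sequence_length``, ties broken by
    lexicographically smallest ``protein_id``. Replaces CD-HIT-style
    redundancy removal with a deterministic per-gene policy."""
    best: dict[str, ProteinRecord] = {}
    for rec in proteins:
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or rec.sequence_length > cur.sequence_length
            or (rec.sequence_length == cur.sequence_length and rec.protein_id < cur.protein_id)
        ):
            best[rec.gene_id] = rec
    return [best[g] for g in sorted(best)]


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA whose descriptions carry ``gene=<gene_id>``.

    Without a tag the gene id defaults to the protein id (one-isoform genes).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene_id = token[len("gene="):]
        if rec.id in seen:
            raise ValidationError(f"duplicate protein id {rec.id}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, gene_id, len(rec.seq)))
    return records


def write_protein_fasta(
    records: Sequence[ProteinRecord], sequences: dict[str, str], path: str | Path
) -> None:
    seqs = [
        SeqRecord(Seq(sequences[r.protein_id]), id=r.protein_id,
                  description=f"gene={r.gene_id}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_bed(path: str | Path) -> list[GeneLocus]:
    """Read gene loci from a BED file (name column = gene id)."""
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                loci.append(
                    GeneLocus(fields[3], fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_bed(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chromosome}\t{loc.start}\t{loc.end}\t{loc.gene_id}\t0\t{loc.strand}\n")


def read_expression_table(
    path: str | Path,
    stage_order: Sequence[str] = STAGES,
    collapse_replicates: bool = True,
) -> pd.DataFrame:
    """Read a gene × stage FPKM table (TSV, first column = gene id).

    Replicate columns named ``<stage>_r<k>`` are averaged per stage when
    ``collapse_replicates`` is set. Columns are returned in ``stage_order``;
    a stage missing from the header is an error, as are negative values and
    duplicate gene ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups}")
    if (df.values < 0).any():
        raise ValidationError("negative FPKM values in expression table")
    if collapse_replicates and any("_r" in c for c in df.columns):
        stage_of = {c: c.rsplit("_r", 1)[0] for c in df.columns}
        df = df.T.groupby(df.columns.map(stage_of), sort=False).mean().T
    missing = [s for s in stage_order if s not in df.columns]
    if missing:
        raise ValidationError(f"stages missing from header: {missing}")
    return df.loc[:, list(stage_order)]


def write_expression_table(matrix: pd.DataFrame, path: str | Path) -> None:
    # %.17g keeps the write->read round trip bitwise exact
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


@dataclass
class PaperFixtures:
    """The packaged census fixtures.

    ``table1`` is the 76-family × 9-species count matrix; ``table2`` is the
    61-family × 9-module count table (columns in the published module order),
    with rows whose printed total disagrees with the printed cells listed in
    ``table2_inconsistent_rows`` and kept as printed.
    """

    table1: FamilyCountMatrix
    table2: pd.DataFrame
    table2_inconsistent_rows: list[str] = field(default_factory=list)


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("tfcensus") / "data" / name))


def load_paper_fixtures() -> PaperFixtures:
    """Load the packaged family-count fixtures (census Table 1/2 shapes)."""
    t1 = pd.read_csv(_data_path("table1.tsv"), sep="\t", dtype={"superfamily": str})
    t1["superfamily"] = t1["superfamily"].fillna("")
    species = [c for c in t1.columns if c not in ("superfamily", "family")]
    counts = t1.set_index("family")[species].astype(int)
    superfamily = t1.set_index("family")["superfamily"]
    table1 = FamilyCountMatrix(counts, superfamily=superfamily)

    t2 = pd.read_csv(_data_path("table2.tsv"), sep="\t", index_col="family")
    modules = [c for c in t2.columns if c != "printed_total"]
    bad = t2.index[t2[modules].sum(axis=1) != t2["printed_total"]].tolist()
    return PaperFixtures(table1=table1, table2=t2[modules].astype(int),
                         table2_inconsistent_rows=bad)
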