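"""Pipeline orchestration: chained stages, a run manifest, and the
published-number self-check table.

``run_pipeline`` chains classify → census → modules → hox on whatever
inputs the configuration provides, writing each stage's output as TSV next
to a machine-readable manifest (parameters, input checksums). Stages the
configuration does not describe are skipped; a stage failure aborts the
run with the failing stage named and a FAILED marker on disk.

``paper_checks`` recomputes every count, fraction and set-algebra quantity
derivable from the packaged census fixtures and compares it with the
published value.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, census, coexpression, collinearity
from .classifier import FamilyRuleSet, classify_proteome, default_rules, read_rules
from .coexpression import ModuleDetectionParams
from .io_formats import (
    STAGES,
    load_paper_fixtures,
    parse_domtblout,
    read_bed,
    read_expression_table,
    read_protein_fasta,
)


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run; unset paths skip the stage."""

    out_dir: str = "tfcensus_out"
    domtbl: str | None = None
    proteins: str | None = None
    rules: str | None = None
    expression: str | None = None
    hox_bed: str | None = None
    hox_pg: str | None = None
    soft_power: float = 12.0
    min_module_size: int = 300
    cut_height: float = 0.99
    network_sign: str = "unsigned"
    expressed_fpkm: float = 10.0
    onset_fpkm: float = 10.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def module_params(self) -> ModuleDetectionParams:
        return ModuleDetectionParams(
            soft_power=self.soft_power,
            min_module_size=self.min_module_size,
            cut_height=self.cut_height,
            network_sign=self.network_sign,
        )


@dataclass
class PipelineReport:
    out_dir: Path
    stages_run: list[str] = field(default_factory=list)
    assignments: list | None = None
    partition: coexpression.ModulePartition | None = None
    stc: list | None = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage the configuration describes; outputs are deterministic
    for a fixed configuration and seed (the manifest records both)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out)
    rules: FamilyRuleSet = read_rules(config.rules) if config.rules else default_rules()
    inputs = {
        k: v
        for k, v in (("domtbl", config.domtbl), ("proteins", config.proteins),
                     ("rules", config.rules), ("expression", config.expression),
                     ("hox_bed", config.hox_bed), ("hox_pg", config.hox_pg))
        if v
    }
    manifest = {
        "tfcensus_version": __version__,
        "parameters": asdict(config),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
    }

    def run_stage(name, fn):
        try:
            fn()
            report.stages_run.append(name)
        except Exception as exc:
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    if config.domtbl and config.proteins:
        def classify():
            hits = parse_domtblout(config.domtbl)
            proteins = read_protein_fasta(config.proteins)
            assigns = classify_proteome(hits, proteins, rules)
            report.assignments = assigns
            pd.DataFrame(
                [
                    {
                        "gene_id": a.gene_id,
                        "family": a.family,
                        "superfamily": a.superfamily or "",
                        "subtype": a.subtype or "",
                        "best_evalue": a.best_evalue,
                        "candidate_families": ",".join(sorted(a.candidate_families)),
                    }
                    for a in assigns
                ]
            ).to_csv(out / "assignments.tsv", sep="\t", index=False)
            matrix = census.build_count_matrix(
                {"sample": assigns}, all_families=rules.families
            )
            matrix.counts.to_csv(out / "family_counts.tsv", sep="\t",
                                 index_label="family")
        run_stage("classify", classify)

    if config.expression:
        def modules():
            expr = read_expression_table(config.expression)
            params = config.module_params()
            network = coexpression.build_network(expr, params)
            partition = coexpression.detect_modules(network, params)
            partition = coexpression.assign_groups(partition, expr)
            report.partition = partition
            pd.DataFrame(
                {
                    "gene_id": partition.labels.index,
                    "module": partition.labels.values,
                    "group": [
                        partition.groups.get(m, "") for m in partition.labels.values
                    ],
                }
            ).to_csv(out / "modules.tsv", sep="\t", index=False)
            if report.assignments:
                family_of = {a.gene_id: a.family for a in report.assignments}
                if all(g in family_of for g in partition.labels.index):
                    coexpression.family_module_table(partition, family_of).to_csv(
                        out / "family_modules.tsv", sep="\t"
                    )
        run_stage("modules", modules)

    if config.hox_bed and config.hox_pg and config.expression:
        def hox():
            loci = {l.gene_id: l for l in read_bed(config.hox_bed)}
            pg = pd.read_csv(config.hox_pg, sep="\t").set_index("gene_id")[
                "paralog_group"
            ]
            expr = read_expression_table(config.expression)
            cluster = sorted(
                (
                    collinearity.ClusterGene(
                        g,
                        int(pg[g]) if g in pg.index else None,
                        loci[g],
                        collinearity.onset_stage(g, expr, config.onset_fpkm)
                        if g in expr.index
                        else None,
                    )
                    for g in loci
                ),
                key=lambda cg: (cg.locus.chromosome, cg.locus.start),
            )
            stc = collinearity.find_collinear_subclusters(cluster)
            report.stc = stc
            pd.DataFrame(
                [
                    {
                        "genes": ",".join(r.gene_ids),
                        "tau": r.tau,
                        "orientation": r.orientation,
                    }
                    for r in stc
                ]
            ).to_csv(out / "stc.tsv", sep="\t", index=False)
        run_stage("hox", hox)

    report.manifest = manifest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# published-number self-checks

_CHORDATE_PANEL = ["S. clava", "H. sapiens", "B. floridae", "C. elegans"]
_ASCIDIAN_PANEL = ["S. clava", "C. robusta", "M. oculata", "B. leachii", "B. schlosseri"]
_EXCLUSIVE_CHORDATE = {
    "PC4", "CSRNP_N", "DM", "CBFB_NFYA", "HTH_psq", "HSF_DNA-binding", "zf-MIZ",
}


def fixture_quantities() -> dict[str, float]:
    """Every count, fraction and set size the packaged fixtures determine."""
    fx = load_paper_fixtures()
    t1 = fx.table1
    common, only_a, only_b = census.exclusive_shared(
        t1, _CHORDATE_PANEL, _ASCIDIAN_PANEL
    )
    return {
        "sclava_total_tfs": census.total_tfs(t1, "S. clava"),
        "sclava_total_families": census.total_families(t1, "S. clava"),
        "zfc2h2_fraction_pct": census.family_fraction(t1, "zf-C2H2", "S. clava"),
        "homeodomain_fraction_pct": census.family_fraction(t1, "Homeodomain", "S. clava"),
        "zfc2h2_expansion_vs_crobusta": census.family_expansion(
            t1, "zf-C2H2", "S. clava", "C. robusta"
        ),
        "zfc2h2_expansion_vs_odioica": census.family_expansion(
            t1, "zf-C2H2", "S. clava", "O. dioica"
        ),
        "zfc2h2_expansion_vs_bleachii": census.family_expansion(
            t1, "zf-C2H2", "S. clava", "B. leachii"
        ),
        "shared_families_chordate_panel": len(census.shared_families(t1, _CHORDATE_PANEL)),
        "shared_families_ascidian_panel": len(census.shared_families(t1, _ASCIDIAN_PANEL)),
        "cross_group_common_families": len(common),
        "chordate_exclusive_families": len(only_a),
        "ascidian_exclusive_families": len(only_b),
        "chordate_exclusive_matches_list": float(only_a == _EXCLUSIVE_CHORDATE),
        "sclava_orphan_families": len(census.orphan_families(t1, "S. clava")),
        "turquoise_module_size": int(fx.table2["turquoise"].sum()),
        "forkhead_module_total": int(fx.table2.loc["Forkhead box"].sum()),
        "maternal_expressed_pct": coexpression.percentage(290, 553),
    }


_EXPECTED = {
    "sclava_total_tfs": 553,
    "sclava_total_families": 60,
    "zfc2h2_fraction_pct": 27.85,
    "homeodomain_fraction_pct": 13.20,
    "zfc2h2_expansion_vs_crobusta": 59,
    "zfc2h2_expansion_vs_odioica": 82,
    "zfc2h2_expansion_vs_bleachii": 44,
    "shared_families_chordate_panel": 51,
    "shared_families_ascidian_panel": 51,
    "cross_group_common_families": 44,
    "chordate_exclusive_families": 7,
    "ascidian_exclusive_families": 7,
    "chordate_exclusive_matches_list": 1.0,
    "sclava_orphan_families": 16,
    "turquoise_module_size": 174,
    "forkhead_module_total": 23,
    "maternal_expressed_pct": 52.44,
}


def paper_checks() -> pd.DataFrame:
    """Recompute every fixture-derivable published number; one row per check
    with the computed value, the published value, and a pass flag."""
    computed = fixture_quantities()
    rows = [
        {
            "check": name,
            "computed": computed[name],
            "published": _EXPECTED[name],
            "pass": computed[name] == _EXPECTED[name],
        }
        for name in _EXPECTED
    ]
    return pd.DataFrame(rows)
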