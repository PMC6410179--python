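"""Full-characterization orchestration from one plain-text (YAML) config.

Stages run in dependency order — classify, physchem, phylo, dupscan,
structure, expr, qpcr — each reading the inputs named in the config and
writing one table under the output directory. The JSON run report records the
package version, seed, thresholds and per-stage row counts; it contains no
timestamps, so the same config and seed give byte-identical reports. The first
failing stage halts the run and is named in the raised error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import famchar
from famchar import core_io, expression, family_assign, gene_structure, phylo, qpcr
from famchar.duplication import DuplicationThresholds, scan_duplications, write_calls
from famchar.physchem import profile_all, summarize_profiles


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Input paths and every stage threshold, with survey defaults."""

    # inputs
    fasta: str = ""
    loci: str = ""
    hits: str = ""
    cds: str = ""
    genomic: str = ""
    alignment: str = ""
    fpkm: str = ""
    ct: str = ""
    # thresholds
    e_value: float = 0.05
    identity_candidate: float = 75.0
    tandem_gap_kb: float = 100.0
    tandem_max_intervening: int = 10
    seg_coverage: float = 80.0
    seg_identity: float = 70.0
    bootstrap_reps: int = 1000
    support_min: float = 90.0
    min_intron: int = 20
    pseudocount: float = 0.00001
    fc_threshold: float = 1.0
    control_condition: str = ""  # default: first column of the FPKM table
    reference_gene: str = "StEF1a"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.e_value > 0, "e_value must be > 0"),
            (0 < self.identity_candidate <= 100, "identity_candidate in (0, 100]"),
            (self.tandem_gap_kb > 0, "tandem_gap_kb must be > 0"),
            (self.tandem_max_intervening >= 1, "tandem_max_intervening must be >= 1"),
            (0 < self.seg_coverage <= 100, "seg_coverage in (0, 100]"),
            (0 < self.seg_identity <= 100, "seg_identity in (0, 100]"),
            (self.bootstrap_reps >= 1, "bootstrap_reps must be >= 1"),
            (0 <= self.support_min <= 100, "support_min in [0, 100]"),
            (self.min_intron >= 1, "min_intron must be >= 1"),
            (self.pseudocount > 0, "pseudocount must be > 0"),
            (self.fc_threshold > 0, "fc_threshold must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def duplication_thresholds(self) -> DuplicationThresholds:
        return DuplicationThresholds(
            identity_candidate=self.identity_candidate,
            tandem_gap_kb=self.tandem_gap_kb,
            tandem_max_intervening=self.tandem_max_intervening,
            seg_coverage=self.seg_coverage,
            seg_identity=self.seg_identity,
        )


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage whose inputs are configured; return the run report.

    Raises :class:`StageError` naming the first failing stage. Missing input
    files fail in the loading stage (core_io), before any computation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "famchar",
        "version": famchar.__version__,
        "seed": config.seed,
        "thresholds": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("fasta", "loci", "hits", "cds", "genomic", "alignment", "fpkm", "ct")
        },
        "stages": {},
    }

    def stage(name: str):
        def record(rows: int, **extra) -> None:
            report["stages"][name] = {"status": "ok", "rows": rows, **extra}

        return record

    # --- core_io: load everything up front --------------------------------
    try:
        proteins = core_io.read_fasta(config.fasta) if config.fasta else None
        loci = core_io.read_locus_table(config.loci) if config.loci else None
        hits = core_io.read_hit_table(config.hits) if config.hits else None
        cds = core_io.read_dna_fasta(config.cds) if config.cds else None
        genomic = core_io.read_dna_fasta(config.genomic) if config.genomic else None
        aln = phylo.read_alignment(config.alignment) if config.alignment else None
        fpkm = core_io.read_expression_table(config.fpkm) if config.fpkm else None
        ct = core_io.read_ct_table(config.ct, config.reference_gene) if config.ct else None
    except (OSError, ValueError) as exc:
        raise StageError("core_io", exc) from exc
    n_inputs = sum(x is not None for x in (proteins, loci, hits, cds, genomic, aln, fpkm, ct))
    stage("core_io")(n_inputs)

    roster = None
    if hits is not None:
        try:
            kept = family_assign.filter_hits(hits, config.e_value)
            roster = family_assign.assign_groups(kept, loci=loci)
            family_assign.write_roster(roster, outdir / "roster.tsv")
            counts = family_assign.roster_counts(roster)
            with open(outdir / "roster_counts.json", "w", encoding="utf-8") as fh:
                json.dump(counts, fh, indent=2, sort_keys=True)
        except (OSError, ValueError) as exc:
            raise StageError("classify", exc) from exc
        stage("classify")(len(roster), counts={k: v for k, v in counts.items() if v})

    if proteins is not None:
        try:
            profiles = profile_all(proteins)
            with open(outdir / "profiles.tsv", "w", encoding="utf-8") as fh:
                fh.write("id\tlength\tmw\tpi\tinstability\taliphatic\tgravy\n")
                for p in profiles:
                    fh.write(
                        f"{p.id}\t{p.length}\t{p.mw:.2f}\t{p.pi:.2f}"
                        f"\t{p.instability:.2f}\t{p.aliphatic:.2f}\t{p.gravy:.3f}\n"
                    )
            if roster is not None:
                groups = {gid: e.group for gid, e in roster.entries.items()}
                in_roster = [p for p in profiles if p.id in groups]
                if in_roster:
                    summary = summarize_profiles(in_roster, groups)
                    with open(outdir / "physchem_summary.json", "w", encoding="utf-8") as fh:
                        json.dump(dataclasses.asdict(summary), fh, indent=2, sort_keys=True)
        except (OSError, ValueError) as exc:
            raise StageError("physchem", exc) from exc
        stage("physchem")(len(profiles))

    if aln is not None:
        try:
            tree = phylo.bootstrap_support(aln, config.bootstrap_reps, config.seed)
            phylo.write_newick(tree, outdir / "tree.nwk")
            pairs = phylo.find_sister_pairs(tree, config.support_min)
            with open(outdir / "sister_pairs.tsv", "w", encoding="utf-8") as fh:
                fh.write("id_a\tid_b\n")
                for a, b in pairs:
                    fh.write(f"{a}\t{b}\n")
        except (OSError, ValueError) as exc:
            raise StageError("phylo", exc) from exc
        stage("phylo")(
            aln.n_taxa,
            sister_pairs=len(pairs),
            skipped_replicates=tree.skipped_replicates,
        )

    if roster is not None and proteins is not None and loci is not None:
        try:
            calls = scan_duplications(roster, proteins, loci, config.duplication_thresholds())
            write_calls(calls, outdir / "duplications.tsv")
        except (OSError, ValueError) as exc:
            raise StageError("dupscan", exc) from exc
        stage("dupscan")(
            len(calls),
            tandem=sum(c.klass == "tandem" for c in calls),
            segmental=sum(c.klass == "segmental" for c in calls),
        )

    if cds is not None and genomic is not None:
        try:
            strands = {g.gene_id: g.strand for g in loci} if loci else {}
            models = []
            for gid in cds:
                if gid not in genomic:
                    raise ValueError(f"no genomic sequence for {gid!r}")
                models.append(
                    gene_structure.map_cds_to_genome(
                        cds[gid],
                        genomic[gid],
                        gene_id=gid,
                        strand=strands.get(gid, "+"),
                        min_intron=config.min_intron,
                    )
                )
            gene_structure.write_models(models, outdir / "gene_models.tsv")
            hist = gene_structure.intron_distribution(models)
            with open(outdir / "intron_distribution.json", "w", encoding="utf-8") as fh:
                json.dump({str(k): v for k, v in hist.items()}, fh, indent=2, sort_keys=True)
        except (OSError, ValueError) as exc:
            raise StageError("structure", exc) from exc
        stage("structure")(len(models), introns=hist)

    if fpkm is not None:
        try:
            control = config.control_condition or fpkm.conditions[0]
            if control not in fpkm.conditions:
                raise ValueError(f"control condition {control!r} not in the FPKM table")
            pairs_tc = [(c, control) for c in fpkm.conditions if c != control]
            fc = expression.fold_change_table(
                fpkm, pairs_tc, eps=config.pseudocount, threshold=config.fc_threshold
            )
            fc.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
            cv = expression.cv_per_gene(fpkm)
            with open(outdir / "cv_percent.tsv", "w", encoding="utf-8") as fh:
                fh.write("gene_id\tcv_percent\n")
                for gid, v in cv.items():
                    fh.write(f"{gid}\t{v:.2f}\n")
        except (OSError, ValueError) as exc:
            raise StageError("expr", exc) from exc
        stage("expr")(
            len(fc),
            induced=int((fc["response"] == "induced").sum()),
            inhibited=int((fc["response"] == "inhibited").sum()),
        )

    if ct is not None:
        try:
            rel = qpcr.quantify_all(ct)
            qpcr.write_relative_expression(rel, outdir / "relative_expression.tsv")
        except (OSError, ValueError) as exc:
            raise StageError("qpcr", exc) from exc
        stage("qpcr")(len(rel))

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
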