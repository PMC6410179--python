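"""Tandem vs segmental duplication classification for family gene pairs.

A within-group pair first becomes a candidate when the global-alignment
identity of its proteins exceeds 75%. A candidate is a *tandem* duplicate when
both genes sit on the same chromosome within 100 kb (nearest-ends gap,
inclusive bound) with fewer than 10 intervening non-family genes; otherwise it
is a *segmental* duplicate when the aligned region covers more than 80% of the
longer sequence at more than 70% identity; otherwise no call. Tandem is tested
first: it is the more specific event.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from famchar.core_io import GeneLocus, ProteinRecord
from famchar.family_assign import FamilyRoster


@dataclass(frozen=True)
class DuplicationThresholds:
    """All classification cutoffs in one place (percent / kb / counts)."""

    identity_candidate: float = 75.0  # % identity to consider a pair at all
    tandem_gap_kb: float = 100.0  # max nearest-ends gap, inclusive
    tandem_max_intervening: int = 10  # strict upper bound on non-family genes
    seg_coverage: float = 80.0  # % of longer sequence covered, strict
    seg_identity: float = 70.0  # % identity, strict


DEFAULT_THRESHOLDS = DuplicationThresholds()


@dataclass(frozen=True)
class PairAlignmentStats:
    """Identity and coverage of the global alignment of two proteins."""

    id_a: str
    id_b: str
    identity_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0 and 0.0 <= self.coverage_pct <= 100.0):
            raise ValueError("identity/coverage must be in [0, 100]")


@dataclass(frozen=True)
class DuplicationCall:
    """Classification of one candidate pair with its recorded evidence."""

    id_a: str
    id_b: str
    klass: str  # tandem | segmental | none
    identity_pct: float
    coverage_pct: float
    same_chromosome: bool
    gap_bp: int | None  # nearest-ends gap if same chromosome
    intervening: int | None  # non-family genes between, if same chromosome

    def __post_init__(self) -> None:
        if self.klass not in ("tandem", "segmental", "none"):
            raise ValueError(f"bad class {self.klass!r}")
        if self.klass == "tandem" and not self.same_chromosome:
            raise ValueError("tandem call requires same chromosome")


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    # BLOSUM62, gap open 10, extend 0.5: ClustalW-flavoured protein defaults
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_similarity(seq_a: str, seq_b: str, *, id_a: str = "a", id_b: str = "b") -> PairAlignmentStats:
    """Needleman–Wunsch global alignment statistics for a protein pair.

    identity_pct: identical residue pairs / alignment columns x 100 (global
    pairwise alignments contain no double-gap columns). coverage_pct: columns
    where both sequences have a residue / length of the longer sequence x 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    columns = len(row_a)
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    paired = sum(1 for x, y in zip(row_a, row_b) if x != "-" and y != "-")
    return PairAlignmentStats(
        id_a=id_a,
        id_b=id_b,
        identity_pct=100.0 * identical / columns,
        coverage_pct=100.0 * paired / max(len(seq_a), len(seq_b)),
    )


def genomic_gap(locus_a: GeneLocus, locus_b: GeneLocus) -> int:
    """Gap in bp between the nearest ends of two same-chromosome genes (0 if overlapping)."""
    if locus_a.chromosome != locus_b.chromosome:
        raise ValueError("genes are on different chromosomes")
    first, second = sorted((locus_a, locus_b), key=lambda g: (g.start, g.end))
    return max(0, second.start - first.end - 1)


def intervening_gene_count(
    locus_a: GeneLocus, locus_b: GeneLocus, all_loci: Sequence[GeneLocus]
) -> int:
    """Non-family genes lying strictly between two genes' coordinate spans."""
    if locus_a.chromosome != locus_b.chromosome:
        raise ValueError("genes are on different chromosomes")
    first, second = sorted((locus_a, locus_b), key=lambda g: (g.start, g.end))
    lo, hi = first.end, second.start  # interval strictly between the spans
    count = 0
    for g in all_loci:
        if g.chromosome != locus_a.chromosome or g.in_family:
            continue
        if g.gene_id in (locus_a.gene_id, locus_b.gene_id):
            continue
        if g.start > lo and g.end < hi:
            count += 1
    return count


def classify_pair(
    stats: PairAlignmentStats,
    loci: Mapping[str, GeneLocus],
    all_loci: Sequence[GeneLocus],
    thresholds: DuplicationThresholds = DEFAULT_THRESHOLDS,
) -> DuplicationCall:
    """Classify one candidate pair; a pure function of the recorded evidence."""
    try:
        locus_a, locus_b = loci[stats.id_a], loci[stats.id_b]
    except KeyError as exc:
        raise ValueError(f"gene id {exc.args[0]!r} absent from loci") from None

    same_chrom = locus_a.chromosome == locus_b.chromosome
    gap = genomic_gap(locus_a, locus_b) if same_chrom else None
    between = intervening_gene_count(locus_a, locus_b, all_loci) if same_chrom else None

    if (
        same_chrom
        and gap <= thresholds.tandem_gap_kb * 1000
        and between < thresholds.tandem_max_intervening
    ):
        klass = "tandem"
    elif (
        stats.coverage_pct > thresholds.seg_coverage
        and stats.identity_pct > thresholds.seg_identity
    ):
        klass = "segmental"
    else:
        klass = "none"
    return DuplicationCall(
        id_a=stats.id_a,
        id_b=stats.id_b,
        klass=klass,
        identity_pct=stats.identity_pct,
        coverage_pct=stats.coverage_pct,
        same_chromosome=same_chrom,
        gap_bp=gap,
        intervening=between,
    )


def scan_duplications(
    roster: FamilyRoster,
    sequences: Iterable[ProteinRecord],
    all_loci: Sequence[GeneLocus],
    thresholds: DuplicationThresholds = DEFAULT_THRESHOLDS,
) -> list[DuplicationCall]:
    """Evaluate every within-group pair above the candidate identity threshold.

    Output is deterministic (lexicographic pair ids) and invariant to input
    row order.
    """
    seq_by_id = {r.id: r.seq for r in sequences}
    loci_by_id = {g.gene_id: g for g in all_loci}
    for gid in roster.entries:
        if gid not in seq_by_id:
            raise ValueError(f"sequence missing for roster gene {gid!r}")
        if gid not in loci_by_id:
            raise ValueError(f"locus missing for roster gene {gid!r}")

    calls: list[DuplicationCall] = []
    groups: dict[str, list[str]] = {}
    for gid in sorted(roster.entries):
        groups.setdefault(roster.group_of(gid), []).append(gid)
    for group in sorted(groups):
        members = groups[group]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                stats = pairwise_similarity(seq_by_id[a], seq_by_id[b], id_a=a, id_b=b)
                if stats.identity_pct > thresholds.identity_candidate:
                    calls.append(classify_pair(stats, loci_by_id, all_loci, thresholds))
    calls.sort(key=lambda c: (c.id_a, c.id_b))
    return calls


def write_calls(calls: Iterable[DuplicationCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "id_a\tid_b\tclass\tidentity_pct\tcoverage_pct\tsame_chromosome\tgap_bp\tintervening\n"
        )
        for c in calls:
            fh.write(
                f"{c.id_a}\t{c.id_b}\t{c.klass}\t{c.identity_pct:.2f}\t{c.coverage_pct:.2f}"
                f"\t{1 if c.same_chromosome else 0}"
                f"\t{'' if c.gap_bp is None else c.gap_bp}"
                f"\t{'' if c.intervening is None else c.intervening}\n"
            )
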