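"""Exon–intron structure: exact-match spliced mapping of CDS onto genomic DNA.

The mapper chains maximal exact CDS blocks onto the genomic sequence left to
right, enforcing a minimum intron length between consecutive exons. Exact
matching is correct for annotation-consistent sequence pairs (and for the
synthetic genomes the generators produce); it is documented as a limitation
for real, polymorphic data, where a tolerant spliced aligner would be needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

DEFAULT_MIN_INTRON = 20

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AmbiguousMappingError(ValueError):
    """The CDS maps to the genomic sequence along two distinct exon chains."""

    def __init__(self, gene_id: str, chains: Sequence[tuple[tuple[int, int], ...]]):
        self.chains = tuple(chains)
        super().__init__(
            f"{gene_id}: ambiguous CDS mapping; {len(chains)} distinct exon chains: "
            + "; ".join(str(list(c)) for c in chains[:4])
        )


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon intervals on the genomic sequence (1-based inclusive)."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: need >= 1 exon")
        prev_end = 0
        for start, end in self.exons:
            if not (1 <= start <= end):
                raise ValueError(f"{self.gene_id}: bad exon interval {start}..{end}")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be non-overlapping, ascending")
            prev_end = end

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    def spliced(self, genomic: str) -> str:
        """Concatenated exon sequence (must equal the CDS)."""
        return "".join(genomic[s - 1 : e] for s, e in self.exons)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _match_len(cds: str, ci: int, genomic: str, gi: int) -> int:
    n = 0
    while ci + n < len(cds) and gi + n < len(genomic) and cds[ci + n] == genomic[gi + n]:
        n += 1
    return n


def _chains(
    cds: str, genomic: str, ci: int, g_min: int, min_intron: int, budget: list[int]
) -> list[tuple[tuple[int, int], ...]]:
    """All completions of the greedy maximal-block chaining from (ci, g_min).

    At each step only the genomic starts achieving the maximal block length are
    pursued (greedy); several distinct completions constitute an ambiguity.
    ``budget`` caps the total number of recursion steps.
    """
    if ci == len(cds):
        return [()]
    if budget[0] <= 0:
        raise ValueError("mapping search budget exceeded (highly repetitive input)")
    budget[0] -= 1
    best_len = 0
    starts: list[int] = []
    for gi in range(g_min, len(genomic)):
        if genomic[gi] != cds[ci]:
            continue
        m = _match_len(cds, ci, genomic, gi)
        if m > best_len:
            best_len = m
            starts = [gi]
        elif m == best_len:
            starts.append(gi)
    if best_len == 0:
        return []
    out: list[tuple[tuple[int, int], ...]] = []
    for gi in starts[:8]:  # cap fan-out; ambiguity is reported, not enumerated fully
        block = ((gi + 1, gi + best_len),)  # 1-based inclusive
        rest = _chains(cds, genomic, ci + best_len, gi + best_len + min_intron, min_intron, budget)
        out.extend(block + r for r in rest)
    # deduplicate identical chains
    return sorted(set(out))


def map_cds_to_genome(
    cds: str,
    genomic: str,
    *,
    gene_id: str = "gene",
    strand: str = "+",
    min_intron: int = DEFAULT_MIN_INTRON,
) -> GeneModel:
    """Map a CDS onto its genomic sequence by exact-match block chaining.

    Minus-strand genes are reverse-complemented before mapping, so exon
    coordinates refer to the reverse-complemented genomic sequence.
    Raises if the CDS is not fully mappable, or
    :class:`AmbiguousMappingError` when two distinct chains exist.
    """
    cds = cds.upper()
    genomic = genomic.upper()
    if not cds or not genomic:
        raise ValueError(f"{gene_id}: empty sequence")
    if set(cds) - set("ACGT") or set(genomic) - set("ACGT"):
        raise ValueError(f"{gene_id}: sequences must be unambiguous DNA (ACGT)")
    if len(cds) > len(genomic):
        raise ValueError(f"{gene_id}: CDS longer than genomic sequence")
    if strand == "-":
        genomic = reverse_complement(genomic)
    elif strand != "+":
        raise ValueError(f"{gene_id}: strand must be '+' or '-'")

    chains = _chains(cds, genomic, 0, 0, min_intron, [20000])
    if not chains:
        raise ValueError(f"{gene_id}: CDS not fully mappable onto the genomic sequence")
    if len(chains) > 1:
        raise AmbiguousMappingError(gene_id, chains)
    model = GeneModel(gene_id=gene_id, exons=chains[0])
    assert model.spliced(genomic) == cds  # mapping contract
    return model


def intron_distribution(models: Sequence[GeneModel]) -> dict[int, int]:
    """Histogram of intron counts; values sum to the number of models."""
    if not models:
        raise ValueError("need >= 1 gene model")
    hist: dict[int, int] = {}
    for m in models:
        hist[m.intron_count] = hist.get(m.intron_count, 0) + 1
    return dict(sorted(hist.items()))


def write_models(models: Iterable[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tn_exons\tn_introns\texons\n")
        for m in models:
            exon_str = ",".join(f"{s}-{e}" for s, e in m.exons)
            fh.write(f"{m.gene_id}\t{len(m.exons)}\t{m.intron_count}\t{exon_str}\n")
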