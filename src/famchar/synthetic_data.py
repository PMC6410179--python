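"""Seeded generators for family genomes, alignments, FPKM matrices and Ct tables.

Every generator is a pure function of (seed, parameters): identical inputs give
identical outputs, and each emits a truth table sufficient for downstream
recovery tests, so no expectation is ever hard-coded against generator output.

The family generator's defaults emulate the potato LEA survey conditions:
nine groups with sizes {LEA1:5, LEA2:45, LEA3:4, LEA4:3, LEA5:3, LEA6:1,
ASR:4, DHN:5, SMP:4} (74 genes), twelve chromosomes, four tandem pairs, two
segmental pairs, an intron-count split of 39/29/6 genes with 0/1/2 introns,
and the lysine-rich dehydrin K-segment planted verbatim in every DHN protein.
Paralogs diverge by uniform per-site substitution (no indels, no substitution
matrix) — adequate for threshold-crossing tests, not a biological model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from famchar.core_io import (
    CtRecord,
    DomainHit,
    ExpressionMatrix,
    GeneLocus,
    ProteinRecord,
    write_ct_table,
    write_dna_fasta,
    write_expression_table,
    write_fasta,
    write_hit_table,
    write_locus_table,
)
from famchar.phylo import Alignment

AA = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

#: Lysine-rich dehydrin K-segment, planted verbatim in every DHN sequence.
K_SEGMENT = "EKGMMEKIKEKLPGHH"

#: Group sizes of the surveyed family (74 genes in nine groups).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "LEA1": 5, "LEA2": 45, "LEA3": 4, "LEA4": 3, "LEA5": 3,
    "LEA6": 1, "ASR": 4, "DHN": 5, "SMP": 4,
}

#: Group -> Pfam accession (inverse of the assignment map).
GROUP_PFAM: dict[str, str] = {
    "LEA1": "PF03760", "LEA2": "PF03168", "LEA3": "PF03242", "LEA4": "PF02987",
    "LEA5": "PF00477", "LEA6": "PF10714", "ASR": "PF02496", "DHN": "PF00257",
    "SMP": "PF04927",
}

#: 0/1/2-intron gene counts of the surveyed family.
DEFAULT_INTRON_SPLIT = (39, 29, 6)


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, frozen: range | None = None
) -> str:
    """Per-site substitution at ``rate``, uniform over the 19 alternatives.

    Positions inside ``frozen`` (a planted motif) are never touched.
    """
    out = list(seq)
    for i in range(len(out)):
        if frozen is not None and i in frozen:
            continue
        if rng.random() < rate:
            alternatives = AA.replace(out[i], "")
            out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


@dataclass
class TruthTable:
    """Planted ground truth serialized alongside generator outputs."""

    seed: int
    group_members: dict[str, list[str]] = field(default_factory=dict)
    tandem_pairs: list[tuple[str, str]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str]] = field(default_factory=list)
    intron_counts: dict[str, int] = field(default_factory=dict)
    motifs: dict[str, str] = field(default_factory=dict)
    excluded_genes: list[str] = field(default_factory=list)
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_rel: dict[str, dict[str, float]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class FamilyBundle:
    """Everything `simulate_family` produces, in memory."""

    proteins: list[ProteinRecord]
    loci: list[GeneLocus]
    hits: list[DomainHit]
    cds: dict[str, str]
    genomic: dict[str, str]
    exon_truth: dict[str, list[tuple[int, int]]]
    alignments: dict[str, Alignment]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.faa")
        write_locus_table(self.loci, outdir / "loci.tsv")
        write_hit_table(self.hits, outdir / "hits.tsv")
        write_dna_fasta(self.cds, outdir / "cds.fna")
        write_dna_fasta(self.genomic, outdir / "genomic.fna")
        largest = max(self.alignments, key=lambda g: self.alignments[g].n_taxa)
        aln = self.alignments[largest]
        with open(outdir / "alignment.afa", "w", encoding="utf-8") as fh:
            for name, row in zip(aln.ids, aln.rows):
                fh.write(f">{name}\n{row}\n")
        self.truth.to_json(outdir / "truth.json")


def simulate_family(
    seed: int,
    n_per_group: Mapping[str, int] | None = None,
    divergence: float = 0.30,
    n_tandem_arrays: int = 4,
    n_segmental_pairs: int = 2,
    n_chromosomes: int = 12,
    *,
    pair_divergence: float = 0.03,
    segmental_divergence: float = 0.08,
    n_decoy_genes: int = 10,
    intron_split: tuple[int, int, int] = DEFAULT_INTRON_SPLIT,
    min_intron: int = 50,
    max_intron: int = 300,
) -> FamilyBundle:
    """Simulate a multi-group protein family with planted duplications.

    Each group is seeded from a random ancestor (150–400 residues) carrying a
    frozen group-specific motif (the K-segment for DHN); members are generated
    by copy + per-site substitution at ``divergence``. Tandem pairs are placed
    on one chromosome within 100 kb with < 10 interleaved non-family genes;
    segmental pairs are low-divergence copies on different chromosomes. Domain
    hits carry e-values below 0.05 for true members; decoy genes get either a
    non-family accession or an above-threshold e-value, per the truth table.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError(f"divergence must be in [0, 0.5], got {divergence}")
    if n_chromosomes < 2:
        raise ValueError("need >= 2 chromosomes")
    sizes = dict(n_per_group) if n_per_group is not None else dict(DEFAULT_GROUP_SIZES)
    if any(v < 1 for v in sizes.values()):
        raise ValueError("group sizes must be >= 1")

    rng = np.random.default_rng(seed)
    truth = TruthTable(
        seed=seed,
        params={
            "divergence": divergence,
            "pair_divergence": pair_divergence,
            "segmental_divergence": segmental_divergence,
            "n_tandem_arrays": n_tandem_arrays,
            "n_segmental_pairs": n_segmental_pairs,
            "n_chromosomes": n_chromosomes,
        },
    )

    # --- group ancestors with frozen motifs -------------------------------
    ancestors: dict[str, str] = {}
    motif_spans: dict[str, range] = {}
    for group in sorted(sizes):
        length = int(rng.integers(150, 401))
        motif = K_SEGMENT if group == "DHN" else _random_seq(rng, AA, 12)
        pos = int(rng.integers(10, length - len(motif) - 10))
        body = _random_seq(rng, AA, length)
        ancestors[group] = body[:pos] + motif + body[pos + len(motif):]
        motif_spans[group] = range(pos, pos + len(motif))
        truth.motifs[group] = motif

    # --- choose which member slots form planted pairs ---------------------
    # tandem donors cycle over the groups with >= 2 members, largest last so
    # the default (4 arrays, 2 segmental) mirrors the surveyed family's
    # ASR / LEA2 / SMP / LEA2 tandem pairs and LEA2 segmental pairs
    multi = sorted([g for g, n in sizes.items() if n >= 2], key=lambda g: (sizes[g], g))
    if n_tandem_arrays + n_segmental_pairs > 0 and not multi:
        raise ValueError("planted pairs require a group with >= 2 members")
    capacity = {g: sizes[g] // 2 for g in multi}
    tandem_groups: list[str] = []
    seg_groups: list[str] = []
    order = sorted(multi, key=lambda g: (-sizes[g], g))
    k = 0
    for _ in range(n_tandem_arrays):
        while capacity[order[k % len(order)]] == 0:
            k += 1
        g = order[k % len(order)]
        tandem_groups.append(g)
        capacity[g] -= 1
        k += 1
    for _ in range(n_segmental_pairs):
        while capacity[order[k % len(order)]] == 0:
            k += 1
        g = order[k % len(order)]
        seg_groups.append(g)
        capacity[g] -= 1
        k += 1

    # --- generate members --------------------------------------------------
    proteins: list[ProteinRecord] = []
    gene_group: dict[str, str] = {}
    idx = 0

    def new_member(group: str, seq: str, name: str) -> str:
        nonlocal idx
        idx += 1
        gid = f"SYNG{idx:04d}"
        proteins.append(ProteinRecord(id=gid, seq=seq, name=name, group=group))
        gene_group[gid] = group
        truth.group_members.setdefault(group, []).append(gid)
        return gid

    pair_plan: list[tuple[str, str, str]] = [("tandem", g, f"T{i}") for i, g in enumerate(tandem_groups)]
    pair_plan += [("segmental", g, f"S{i}") for i, g in enumerate(seg_groups)]

    remaining = dict(sizes)
    planted: list[tuple[str, str, str]] = []  # (kind, gid_a, gid_b)
    for kind, group, _tag in pair_plan:
        anc, span = ancestors[group], motif_spans[group]
        n_before = len(truth.group_members.get(group, []))
        base = _mutate(rng, anc, divergence, span)
        rate = pair_divergence if kind == "tandem" else segmental_divergence
        copy = _mutate(rng, base, rate, span)
        a = new_member(group, base, f"{group}-{n_before + 1}")
        b = new_member(group, copy, f"{group}-{n_before + 2}")
        planted.append((kind, a, b))
        remaining[group] -= 2
        if kind == "tandem":
            truth.tandem_pairs.append((a, b))
        else:
            truth.segmental_pairs.append((a, b))
    for group in sorted(sizes):
        anc, span = ancestors[group], motif_spans[group]
        for _ in range(remaining[group]):
            n_before = len(truth.group_members.get(group, []))
            new_member(group, _mutate(rng, anc, divergence, span), f"{group}-{n_before + 1}")

    # --- gene structure: CDS + genomic with planted introns ----------------
    n_genes = len(proteins)
    intron_counts = _intron_assignment(rng, n_genes, intron_split)
    cds: dict[str, str] = {}
    genomic: dict[str, str] = {}
    exon_truth: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    for rec, n_introns in zip(proteins, intron_counts):
        c = _random_seq(rng, DNA, 3 * len(rec.seq))
        g, exons = _plant_introns(rng, c, n_introns, min_intron, max_intron)
        strand = "+" if rng.random() < 0.5 else "-"
        cds[rec.id] = c
        # the locus file stores the forward-strand sequence; minus-strand
        # genes are reverse-complemented back before mapping
        genomic[rec.id] = g if strand == "+" else _revcomp(g)
        exon_truth[rec.id] = exons
        strands[rec.id] = strand
        truth.intron_counts[rec.id] = n_introns

    # --- chromosome placement ----------------------------------------------
    loci: list[GeneLocus] = []
    placed: set[str] = set()
    slot_counter = {c: 0 for c in range(1, n_chromosomes + 1)}

    def place(gid: str, chrom: int, start: int) -> GeneLocus:
        placed.add(gid)
        locus = GeneLocus(
            gene_id=gid,
            chromosome=f"chr{chrom:02d}",
            start=start,
            end=start + len(genomic[gid]) - 1,
            strand=strands.get(gid, "+"),
            in_family=gid in gene_group,
        )
        loci.append(locus)
        return locus

    decoy_idx = 0

    def new_decoy(chrom: int, start: int, length: int) -> str:
        nonlocal decoy_idx
        decoy_idx += 1
        gid = f"SYNB{decoy_idx:04d}"
        placed.add(gid)
        loci.append(
            GeneLocus(gene_id=gid, chromosome=f"chr{chrom:02d}", start=start,
                      end=start + length - 1, strand="+", in_family=False)
        )
        return gid

    tandem_band = 200_000_000
    for t, (kind, a, b) in enumerate(planted):
        if kind != "tandem":
            continue
        chrom = [4, 8, 9, 10][t % 4] if n_chromosomes >= 10 else (t % n_chromosomes) + 1
        gap = int(rng.integers(5_000, 80_001))
        n_between = int(rng.integers(0, 10))
        start_a = tandem_band + t * 1_000_000
        locus_a = place(a, chrom, start_a)
        place(b, chrom, locus_a.end + 1 + gap)
        # interleave non-family genes strictly inside the gap
        if n_between:
            step = gap // (n_between + 1)
            glen = min(200, max(50, step // 2))
            for i in range(n_between):
                new_decoy(chrom, locus_a.end + 2 + (i + 1) * step - glen, glen)

    seg_pairs = [(a, b) for kind, a, b in planted if kind == "segmental"]
    for s, (a, b) in enumerate(seg_pairs):
        c1 = (2 * s) % n_chromosomes + 1
        c2 = (2 * s + 1) % n_chromosomes + 1
        place(a, c1, 1_000_000 + slot_counter[c1] * 500_000)
        slot_counter[c1] += 1
        place(b, c2, 1_000_000 + slot_counter[c2] * 500_000)
        slot_counter[c2] += 1

    chrom_cycle = 0
    for rec in proteins:
        if rec.id in placed:
            continue
        chrom = chrom_cycle % n_chromosomes + 1
        chrom_cycle += 1
        place(rec.id, chrom, 1_000_000 + slot_counter[chrom] * 500_000)
        slot_counter[chrom] += 1

    # scattered non-family background genes, far from every family gene
    for i in range(n_decoy_genes):
        chrom = i % n_chromosomes + 1
        new_decoy(chrom, 400_000_000 + (i // n_chromosomes) * 1_000_000, 900)

    loci.sort(key=lambda g: (g.chromosome, g.start, g.end, g.gene_id))

    # --- domain hits ---------------------------------------------------------
    hits: list[DomainHit] = []
    for rec in proteins:
        e = 10.0 ** (-float(rng.uniform(6, 40)))
        hits.append(DomainHit(rec.id, GROUP_PFAM[rec.group], e))
    decoy_ids = [g.gene_id for g in loci if g.gene_id.startswith("SYNB")]
    for i, gid in enumerate(decoy_ids[:n_decoy_genes]):
        if i % 2 == 0:  # non-family accession, good e-value -> excluded
            hits.append(DomainHit(gid, "PF00001", 10.0 ** (-float(rng.uniform(6, 40)))))
        else:  # family accession but e-value above the 0.05 filter -> excluded
            hits.append(DomainHit(gid, GROUP_PFAM["LEA2"], float(rng.uniform(0.05, 1.0))))
        truth.excluded_genes.append(gid)

    # --- per-group alignments (no indels, so rows are already aligned) ------
    alignments = {
        group: Alignment(
            tuple(truth.group_members[group]),
            tuple(next(p.seq for p in proteins if p.id == gid) for gid in truth.group_members[group]),
        )
        for group in sorted(truth.group_members)
        if len(truth.group_members[group]) >= 1
    }

    return FamilyBundle(
        proteins=proteins,
        loci=loci,
        hits=hits,
        cds=cds,
        genomic=genomic,
        exon_truth=exon_truth,
        alignments=alignments,
        truth=truth,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _intron_assignment(
    rng: np.random.Generator, n_genes: int, split: tuple[int, int, int]
) -> list[int]:
    """Intron counts per gene honouring the 0/1/2 split (rescaled if needed)."""
    total = sum(split)
    if n_genes == total:
        counts = [0] * split[0] + [1] * split[1] + [2] * split[2]
    else:
        probs = np.array(split, dtype=float) / total
        counts = list(rng.choice([0, 1, 2], size=n_genes, p=probs))
    counts = [int(c) for c in counts]
    rng.shuffle(counts)
    return counts


def _plant_introns(
    rng: np.random.Generator, cds: str, n_introns: int, min_intron: int, max_intron: int
) -> tuple[str, list[tuple[int, int]]]:
    """Insert ``n_introns`` random-sequence introns at uniform CDS positions.

    Breakpoints keep every exon >= 30 bp, and each intron's first base is
    forced to differ from the next exon's first base so exact-match chaining
    stops precisely at the boundary. Returns (genomic, exon intervals 1-based).
    """
    min_exon = 30
    if n_introns == 0:
        return cds, [(1, len(cds))]
    if len(cds) < (n_introns + 1) * min_exon:
        raise ValueError("CDS too short for the requested intron count")
    cuts = sorted(
        rng.choice(
            np.arange(min_exon, len(cds) - min_exon + 1),
            size=n_introns,
            replace=False,
        )
    )
    # enforce exon length >= min_exon between consecutive cuts
    for i in range(1, len(cuts)):
        if cuts[i] - cuts[i - 1] < min_exon:
            cuts[i] = cuts[i - 1] + min_exon
    if cuts and cuts[-1] > len(cds) - min_exon:
        raise ValueError("could not place introns with the minimum exon length")

    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    prev = 0
    gpos = 0
    for cut in list(cuts) + [len(cds)]:
        exon = cds[prev:cut]
        exons.append((gpos + 1, gpos + len(exon)))
        pieces.append(exon)
        gpos += len(exon)
        if cut < len(cds):
            ilen = int(rng.integers(min_intron, max_intron + 1))
            intron = _random_seq(rng, DNA, ilen)
            banned = cds[cut]  # next exon's first base
            if intron[0] == banned:
                intron = DNA.replace(banned, "")[rng.integers(3)] + intron[1:]
            pieces.append(intron)
            gpos += ilen
        prev = cut
    return "".join(pieces), exons


# ---------------------------------------------------------------------------
# Sister-pair alignment generator
# ---------------------------------------------------------------------------


def simulate_sister_alignment(
    seed: int,
    n_background: int = 8,
    k_pairs: int = 3,
    length: int = 200,
    background_divergence: float = 0.30,
    pair_divergence: float = 0.02,
) -> tuple[Alignment, list[tuple[str, str]]]:
    """Alignment with ``k_pairs`` planted recent duplications among a diverged
    background; returns (alignment, planted sister pairs, sorted)."""
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, AA, length)
    ids: list[str] = []
    rows: list[str] = []
    pairs: list[tuple[str, str]] = []
    for i in range(n_background):
        ids.append(f"BG{i + 1:02d}")
        rows.append(_mutate(rng, ancestor, background_divergence))
    for i in range(k_pairs):
        base = _mutate(rng, ancestor, background_divergence)
        a, b = f"DUP{i + 1}a", f"DUP{i + 1}b"
        ids.extend([a, b])
        rows.extend([base, _mutate(rng, base, pair_divergence)])
        pairs.append((a, b))
    return Alignment(tuple(ids), tuple(rows)), sorted(pairs)


# ---------------------------------------------------------------------------
# Expression and Ct generators
# ---------------------------------------------------------------------------


def simulate_expression(
    seed: int,
    genes: Sequence[str] | int = 74,
    conditions: Sequence[str] = ("control", "treatment"),
    planted_effects: Mapping[str, Mapping[str, float]] | None = None,
    noise: float = 0.1,
    *,
    base_mean: float = 50.0,
    base_sigma: float = 1.0,
    dropout_genes: Sequence[str] = (),
) -> tuple[ExpressionMatrix, TruthTable]:
    """FPKM matrix with planted log2 effects.

    The first condition is the control; for every other condition,
    treatment = control x 2^delta x lognormal(0, noise). ``planted_effects``
    maps gene -> {condition: delta}; when omitted, deltas are drawn once from
    U(-4, 4). Dropout genes get 0 FPKM in every condition.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    if base_mean <= 0:
        raise ValueError("base FPKM level must be > 0")
    if len(conditions) < 2:
        raise ValueError("need a control plus >= 1 treatment condition")
    rng = np.random.default_rng(seed)
    gene_ids = [f"GENE{i + 1:04d}" for i in range(genes)] if isinstance(genes, int) else list(genes)
    control, treatments = conditions[0], list(conditions[1:])

    if planted_effects is None:
        planted_effects = {
            g: {t: float(rng.uniform(-4, 4)) for t in treatments} for g in gene_ids
        }
    truth = TruthTable(seed=seed, params={"noise": noise, "control": control})
    truth.planted_effects = {g: dict(v) for g, v in planted_effects.items()}

    data = {}
    base = base_mean * np.exp(rng.normal(0.0, base_sigma, size=len(gene_ids)) - base_sigma**2 / 2)
    data[control] = base
    for t in treatments:
        deltas = np.array([planted_effects.get(g, {}).get(t, 0.0) for g in gene_ids])
        eps = np.exp(rng.normal(0.0, noise, size=len(gene_ids))) if noise > 0 else 1.0
        data[t] = base * np.exp2(deltas) * eps
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    for g in dropout_genes:
        df.loc[g] = 0.0
        truth.planted_effects.pop(g, None)
    return ExpressionMatrix(df), truth


def simulate_ct(
    seed: int,
    samples: Sequence[str] = ("control", "drought", "salt", "heat", "cold", "zinc"),
    planted_rel: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.2,
    n_reps: int = 3,
    *,
    targets: Sequence[str] = ("DHN-1", "ASR-1", "LEA3-3"),
    reference_gene: str = "StEF1a",
    reference_ct_mean: float = 20.0,
    reference_ct_sd: float = 0.5,
) -> tuple[list[CtRecord], TruthTable]:
    """Replicated Ct table with planted relative expressions.

    The reference Ct is drawn per replicate; the target Ct of a gene with
    planted relative expression r in that replicate is
    ``ct_ref - log2(r) + N(0, noise_sd)``, so 2^-dCt recovers r exactly at
    zero noise. ``planted_rel`` maps sample -> {target: r}; when omitted,
    r is drawn once from 2^U(-3, 4).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_reps < 1:
        raise ValueError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    if planted_rel is None:
        planted_rel = {
            s: {t: float(2.0 ** rng.uniform(-3, 4)) for t in targets} for s in samples
        }
    for s, m in planted_rel.items():
        for t, r in m.items():
            if r <= 0:
                raise ValueError(f"planted relative expression must be > 0 ({s}/{t})")

    truth = TruthTable(seed=seed, params={"noise_sd": noise_sd, "n_reps": n_reps})
    truth.planted_rel = {s: dict(m) for s, m in planted_rel.items()}

    records: list[CtRecord] = []
    for sample in planted_rel:
        ref_cts = reference_ct_mean + rng.normal(0.0, reference_ct_sd, size=n_reps)
        records.append(
            CtRecord(sample, reference_gene, reference_gene, tuple(float(c) for c in ref_cts))
        )
        for target, rel in planted_rel[sample].items():
            noise = rng.normal(0.0, noise_sd, size=n_reps) if noise_sd > 0 else np.zeros(n_reps)
            cts = ref_cts - np.log2(rel) + noise
            records.append(
                CtRecord(sample, target, reference_gene, tuple(float(c) for c in cts))
            )
    return records, truth


def write_expression_bundle(matrix: ExpressionMatrix, truth: TruthTable, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_table(matrix, outdir / "fpkm.tsv")
    truth.to_json(outdir / "truth.json")


def write_ct_bundle(records: list[CtRecord], truth: TruthTable, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ct_table(records, outdir / "ct.csv")
    truth.to_json(outdir / "truth.json")
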