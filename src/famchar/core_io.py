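"""Readers, writers and domain types for every external format the pipeline touches.

Conventions
-----------
* Coordinates are 1-based inclusive (GFF3 convention).
* Tables are tab-separated UTF-8; lines starting with ``#`` are comments.
* The typographic minus sign (U+2212) that appears in transcribed journal
  tables is normalised to ASCII ``-`` on read, and thousands separators in
  numeric fields are dropped.
* Parsers never silently drop rows: every malformed row raises with the line
  number, so record count in = records out + reported errors.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes that ProtParam descriptors are undefined for.
AMBIGUOUS_AA = frozenset("XBZUJO")

#: The nine family groups of the LEA survey.
GROUPS = ("LEA1", "LEA2", "LEA3", "LEA4", "LEA5", "LEA6", "ASR", "DHN", "SMP")

_PFAM_RE = re.compile(r"^PF\d{5}$")
_MINUS = "−"


class FormatError(ValueError):
    """A file violated its format contract (reported with line number)."""


def _normalize_cell(text: str) -> str:
    """ASCII-minus normalisation for transcribed tables."""
    return text.replace(_MINUS, "-").strip()


def _parse_number(text: str, line_no: int, what: str) -> float:
    cell = _normalize_cell(text).replace(",", "")
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"line {line_no}: {what} is not numeric: {text!r}") from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with optional family annotation.

    Parameters
    ----------
    id:
        Accession string, unique within a collection.
    seq:
        Uppercase one-letter amino-acid string over the 20 standard residues.
    name:
        Family label such as ``DHN-3`` (optional).
    group:
        One of :data:`GROUPS` (optional).
    """

    id: str
    seq: str
    name: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.seq) - STANDARD_AA
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)!r}; "
                "only the 20 standard amino acids are accepted"
            )
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"{self.id}: unknown group {self.group!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneLocus:
    """Genomic location of a gene (1-based inclusive coordinates)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    in_family: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.gene_id}: require 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain hit for a gene."""

    gene_id: str
    pfam_acc: str
    e_value: float

    def __post_init__(self) -> None:
        if not _PFAM_RE.match(self.pfam_acc):
            raise ValueError(f"{self.gene_id}: bad Pfam accession {self.pfam_acc!r}")
        if not np.isfinite(self.e_value) or self.e_value < 0:
            raise ValueError(f"{self.gene_id}: e-value must be finite and >= 0")


class ExpressionMatrix:
    """Rectangular genes x conditions matrix of non-negative FPKM values.

    Thin wrapper over a :class:`pandas.DataFrame` (genes as index, condition
    labels as columns) that enforces the FPKM invariants on construction.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene id(s): {dups}")
        if values.columns.has_duplicates:
            raise ValueError("duplicated condition label(s)")
        arr = values.to_numpy(dtype=float)
        if arr.size == 0:
            raise ValueError("expression matrix must be non-empty")
        if np.isnan(arr).any():
            raise ValueError("expression matrix has missing cells")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("FPKM values must be >= 0")
        self._df = values.astype(float)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def conditions(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self._df.equals(other._df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({len(self.genes)} genes x {len(self.conditions)} conditions)"


@dataclass(frozen=True)
class CtRecord:
    """Replicated qPCR cycle-threshold measurements for one (sample, gene)."""

    sample: str
    target_gene: str
    reference_gene: str
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_replicates) < 1:
            raise ValueError(f"{self.sample}/{self.target_gene}: need >= 1 Ct replicate")
        for ct in self.ct_replicates:
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"{self.sample}/{self.target_gene}: Ct values must be finite and > 0, got {ct}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, *, skip_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; input order is preserved. Records containing
    ambiguity codes (X, B, Z, U, J, O) are rejected — or silently skipped when
    ``skip_ambiguous`` is true — because the physicochemical descriptors are
    undefined for them. Any other illegal character is reported with its line
    number.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0
    skip_this = False

    def flush(line_no: int) -> None:
        nonlocal header, chunks, skip_this
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record {header!r} has an empty sequence")
        if not skip_this:
            records.append(ProteinRecord(id=header, seq=seq))
        header, chunks, skip_this = None, [], False

    with open(path, encoding="utf-8") as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if line[1:].split() else ""
                header_line = line_no
                if not header:
                    raise FormatError(f"line {line_no}: empty FASTA header")
                if header in seen:
                    raise FormatError(f"line {line_no}: duplicate id {header!r}")
                seen.add(header)
            else:
                if header is None:
                    raise FormatError(f"line {line_no}: sequence data before any header")
                seq = line.upper()
                bad = set(seq) - STANDARD_AA
                if bad & AMBIGUOUS_AA and skip_ambiguous:
                    skip_this = True
                elif bad:
                    raise FormatError(
                        f"line {line_no}: illegal residue {sorted(bad)[0]!r} in record {header!r}"
                    )
                chunks.append(seq)
        if header is None and not records:
            raise FormatError(f"{path}: empty FASTA file")
        flush(line_no + 1)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, *, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_dna_fasta(path: str | Path) -> dict[str, str]:
    """Read a DNA FASTA into an ordered ``{id: sequence}`` mapping.

    Accepts the unambiguous DNA alphabet only (ACGT, uppercased on read).
    """
    path = Path(path)
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise FormatError(f"line {line_no}: duplicate id {current!r}")
                seqs[current] = []
            else:
                if current is None:
                    raise FormatError(f"line {line_no}: sequence data before any header")
                chunk = line.upper()
                bad = set(chunk) - set("ACGT")
                if bad:
                    raise FormatError(
                        f"line {line_no}: illegal base {sorted(bad)[0]!r} in record {current!r}"
                    )
                seqs[current].append(chunk)
    if not seqs:
        raise FormatError(f"{path}: empty FASTA file")
    out = {k: "".join(v) for k, v in seqs.items()}
    for k, v in out.items():
        if not v:
            raise FormatError(f"record {k!r} has an empty sequence")
    return out


def write_dna_fasta(seqs: Mapping[str, str], path: str | Path, *, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Locus table
# ---------------------------------------------------------------------------

_LOCUS_COLUMNS = ("gene_id", "chromosome", "start", "end", "strand", "in_family")


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a tab-separated gene-locus table; output sorted by (chromosome, start).

    Expected header: ``gene_id  chromosome  start  end  strand  in_family``
    with 1-based inclusive coordinates and in_family in {0,1,true,false}.
    """
    path = Path(path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [_normalize_cell(f) for f in line.split("\t")]
            if header is None:
                header = [f.lower() for f in fields]
                missing = [c for c in _LOCUS_COLUMNS if c not in header]
                if missing:
                    raise FormatError(f"line {line_no}: missing column(s) {missing}")
                continue
            row = dict(zip(header, fields))
            try:
                start = int(row["start"])
                end = int(row["end"])
            except ValueError:
                raise FormatError(
                    f"line {line_no}: non-integer coordinates {row['start']!r}..{row['end']!r}"
                ) from None
            gene_id = row["gene_id"]
            if gene_id in seen:
                raise FormatError(f"line {line_no}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            in_family = row["in_family"].lower() in ("1", "true", "yes")
            try:
                loci.append(
                    GeneLocus(
                        gene_id=gene_id,
                        chromosome=row["chromosome"],
                        start=start,
                        end=end,
                        strand=row["strand"],
                        in_family=in_family,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from None
    if header is None:
        raise FormatError(f"{path}: empty locus table")
    loci.sort(key=lambda g: (g.chromosome, g.start, g.end, g.gene_id))
    return loci


def write_locus_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_LOCUS_COLUMNS) + "\n")
        for g in loci:
            fh.write(
                f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}"
                f"\t{1 if g.in_family else 0}\n"
            )


# ---------------------------------------------------------------------------
# Domain-hit table
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> list[DomainHit]:
    """Read a tab-separated domain-hit table (gene_id, pfam_acc, e_value)."""
    path = Path(path)
    hits: list[DomainHit] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [_normalize_cell(f) for f in line.split("\t")]
            if header is None:
                header = [f.lower() for f in fields]
                for col in ("gene_id", "pfam_acc", "e_value"):
                    if col not in header:
                        raise FormatError(f"line {line_no}: missing column {col!r}")
                continue
            row = dict(zip(header, fields))
            e_value = _parse_number(row["e_value"], line_no, "e_value")
            try:
                hits.append(DomainHit(row["gene_id"], row["pfam_acc"], e_value))
            except ValueError as exc:
                raise FormatError(f"line {line_no}: {exc}") from None
    if header is None:
        raise FormatError(f"{path}: empty hit table")
    return hits


def write_hit_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tpfam_acc\te_value\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.pfam_acc}\t{h.e_value:.6g}\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated FPKM matrix (first column gene ids, header = conditions)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            comment="#",
            encoding="utf-8",
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression table") from None
    # normalise typographic minus in numeric cells before coercion
    df = df.apply(
        lambda col: pd.to_numeric(
            col.map(lambda v: _normalize_cell(v) if isinstance(v, str) else v),
            errors="coerce",
        )
    )
    if df.isna().any().any():
        bad = [str(g) for g in df.index[df.isna().any(axis=1)]]
        raise FormatError(f"{path}: missing or non-numeric cell(s) in row(s) {bad}")
    try:
        return ExpressionMatrix(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="gene_id", encoding="utf-8")


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path, reference_gene: str = "StEF1a") -> list[CtRecord]:
    """Read a long-format qPCR Ct CSV into grouped :class:`CtRecord` objects.

    Expected columns: ``sample, gene, replicate, ct``. Replicates are grouped
    per (sample, gene) in replicate order; every sample must contain rows for
    the reference gene, whose measurements are returned as CtRecords with
    ``target_gene == reference_gene``.
    """
    path = Path(path)
    groups: dict[tuple[str, str], list[tuple[int, float]]] = {}
    order: list[tuple[str, str]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample", "gene", "replicate", "ct"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: CSV must have columns {sorted(required)}")
        for line_no, row in enumerate(reader, start=2):
            sample = row["sample"].strip()
            gene = _normalize_cell(row["gene"])
            try:
                rep = int(row["replicate"])
            except ValueError:
                raise FormatError(f"line {line_no}: non-integer replicate {row['replicate']!r}")
            ct = _parse_number(row["ct"], line_no, "ct")
            if ct <= 0:
                raise FormatError(f"line {line_no}: non-physical Ct {ct} (must be > 0)")
            key = (sample, gene)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((rep, ct))
    if not groups:
        raise FormatError(f"{path}: empty Ct table")
    samples = {s for s, _ in order}
    for sample in sorted(samples):
        if (sample, reference_gene) not in groups:
            raise FormatError(
                f"sample {sample!r} has no rows for reference gene {reference_gene!r}"
            )
    records = []
    for sample, gene in order:
        reps = sorted(groups[(sample, gene)])
        records.append(
            CtRecord(
                sample=sample,
                target_gene=gene,
                reference_gene=reference_gene,
                ct_replicates=tuple(ct for _, ct in reps),
            )
        )
    return records


def write_ct_table(records: Iterable[CtRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "gene", "replicate", "ct"])
        for rec in records:
            for i, ct in enumerate(rec.ct_replicates, start=1):
                writer.writerow([rec.sample, rec.target_gene, i, f"{ct:.6g}"])
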