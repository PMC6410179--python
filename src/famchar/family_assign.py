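"""Domain-based family assignment: Pfam hit table -> nine-group family roster.

The group map is the LEA survey's fixed Pfam-to-group correspondence; genes are
kept when at least one hit passes the e-value filter, assigned to the group of
their best (smallest e-value) mapped hit, and numbered within each group by
chromosomal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from famchar.core_io import GROUPS, DomainHit, GeneLocus

#: Fixed Pfam accession -> family group map.
GROUP_MAP: dict[str, str] = {
    "PF03760": "LEA1",
    "PF03168": "LEA2",
    "PF03242": "LEA3",
    "PF02987": "LEA4",
    "PF00477": "LEA5",
    "PF10714": "LEA6",
    "PF02496": "ASR",
    "PF00257": "DHN",
    "PF04927": "SMP",
}

DEFAULT_EVALUE_THRESHOLD = 0.05


class GroupTieError(ValueError):
    """Two different groups tie on best e-value for one gene.

    Mirrors the manual curation step of the original survey: ties are
    surfaced for resolution, never silently broken.
    """

    def __init__(self, gene_id: str, groups: Sequence[str], e_value: float):
        self.gene_id = gene_id
        self.groups = tuple(sorted(groups))
        self.e_value = e_value
        super().__init__(
            f"gene {gene_id!r}: groups {self.groups} tie at e-value {e_value:g}; "
            "resolve manually"
        )


@dataclass(frozen=True)
class RosterEntry:
    gene_id: str
    group: str
    best_e_value: float
    name: str | None = None  # e.g. "LEA2-7", assigned by chromosomal order


@dataclass
class FamilyRoster:
    """Gene -> (group, best e-value) assignment with per-group sequential names."""

    entries: dict[str, RosterEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def group_of(self, gene_id: str) -> str:
        return self.entries[gene_id].group

    def members(self, group: str) -> list[str]:
        return [e.gene_id for e in self.entries.values() if e.group == group]


def filter_hits(hits: Iterable[DomainHit], threshold: float = DEFAULT_EVALUE_THRESHOLD) -> list[DomainHit]:
    """Keep hits with e-value strictly below ``threshold`` (idempotent)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return [h for h in hits if h.e_value < threshold]


def assign_groups(
    hits: Iterable[DomainHit],
    group_map: Mapping[str, str] = GROUP_MAP,
    loci: Sequence[GeneLocus] | None = None,
) -> FamilyRoster:
    """Build the family roster from (already filtered) domain hits.

    One group per gene: the smallest e-value among hits whose accession maps
    to a group wins; genes whose hits all map to no group are excluded. An
    exact e-value tie between two different groups raises :class:`GroupTieError`.

    When ``loci`` are given, members of each group are named sequentially
    (``LEA2-1`` ...) in (chromosome, start) order; the result is invariant to
    input row order either way.
    """
    best: dict[str, tuple[float, set[str]]] = {}
    for h in sorted(hits, key=lambda h: (h.gene_id, h.e_value, h.pfam_acc)):
        group = group_map.get(h.pfam_acc)
        if group is None:
            continue
        if h.gene_id not in best or h.e_value < best[h.gene_id][0]:
            best[h.gene_id] = (h.e_value, {group})
        elif h.e_value == best[h.gene_id][0]:
            best[h.gene_id][1].add(group)

    roster = FamilyRoster()
    for gene_id in sorted(best):
        e_value, tied = best[gene_id]
        if len(tied) > 1:
            raise GroupTieError(gene_id, sorted(tied), e_value)
        roster.entries[gene_id] = RosterEntry(gene_id, next(iter(tied)), e_value)

    if loci is not None:
        _name_by_position(roster, loci)
    return roster


def _name_by_position(roster: FamilyRoster, loci: Sequence[GeneLocus]) -> None:
    pos = {g.gene_id: (g.chromosome, g.start) for g in loci}
    for group in GROUPS:
        members = roster.members(group)
        members.sort(key=lambda gid: (pos.get(gid, ("~", 0)), gid))
        for i, gid in enumerate(members, start=1):
            old = roster.entries[gid]
            roster.entries[gid] = RosterEntry(gid, old.group, old.best_e_value, f"{group}-{i}")


def roster_counts(roster: FamilyRoster) -> dict[str, int]:
    """Per-group member counts plus ``total``; counts sum to roster size."""
    counts = {g: 0 for g in GROUPS}
    for e in roster.entries.values():
        counts[e.group] += 1
    counts["total"] = len(roster)
    return counts


def write_roster(roster: FamilyRoster, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tname\tgroup\tbest_e_value\n")
        for gid in sorted(roster.entries):
            e = roster.entries[gid]
            fh.write(f"{e.gene_id}\t{e.name or ''}\t{e.group}\t{e.best_e_value:.6g}\n")


def read_roster(path) -> FamilyRoster:
    roster = FamilyRoster()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            roster.entries[f[idx["gene_id"]]] = RosterEntry(
                f[idx["gene_id"]],
                f[idx["group"]],
                float(f[idx["best_e_value"]]),
                f[idx["name"]] or None,
            )
    return roster
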