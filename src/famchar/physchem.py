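"""Protein physicochemical descriptors in the ProtParam tradition.

Implements the five descriptors used to characterise hydrophilic stress
proteins — molecular weight, theoretical isoelectric point, instability
index, aliphatic index and GRAVY — plus the family-level summary statistics
(group means, threshold counts, extremes) reported alongside them.

Constant tables
---------------
* Average (not monoisotopic) residue masses: ExPASy ProtParam reference data.
* Kyte–Doolittle hydropathy values (J. Mol. Biol. 157:105-132, 1982).
* pKa set: Bjellqvist values as used by ProtParam / Biopython.
* DIWV dipeptide instability weights (Guruprasad et al., Protein Eng. 4:155,
  1990) are taken from :mod:`Bio.SeqUtils.ProtParamData` at import time rather
  than re-transcribed (400 entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import DIWV

from famchar.core_io import GROUPS, STANDARD_AA, ProteinRecord

# ExPASy average residue masses (Da); add one water per chain.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa values (ProtParam). Positive groups gain a proton below
# their pKa; negative groups lose one above theirs. Terminal pKa values are
# residue-specific where Bjellqvist measured them.
PKA_POSITIVE: dict[str, float] = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE: dict[str, float] = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERMINAL: dict[str, float] = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
PKA_CTERMINAL: dict[str, float] = {"D": 4.55, "E": 4.75}


def _check_seq(seq: str, *, min_len: int = 1) -> str:
    if len(seq) < min_len:
        raise ValueError(f"sequence must have length >= {min_len}, got {len(seq)}")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)!r}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    _check_seq(seq)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def net_charge(seq: str, ph: float) -> float:
    """Modeled net charge at ``ph`` (Henderson–Hasselbalch per ionisable group)."""
    _check_seq(seq)
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    nterm_pka = PKA_NTERMINAL.get(seq[0], PKA_POSITIVE["Nterm"])
    cterm_pka = PKA_CTERMINAL.get(seq[-1], PKA_NEGATIVE["Cterm"])
    positive = (
        1.0 / (1.0 + 10 ** (ph - nterm_pka))
        + sum(counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa])) for aa in "KRH")
    )
    negative = (
        1.0 / (1.0 + 10 ** (cterm_pka - ph))
        + sum(counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph)) for aa in "DECY")
    )
    return positive - negative


def theoretical_pi(seq: str, *, tol: float = 1e-4) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so bisection converges; iteration
    stops when ``|net_charge| < tol``.
    """
    _check_seq(seq)
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        ph = (lo + hi) / 2.0
        q = net_charge(seq, ph)
        if abs(q) < tol:
            return ph
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def gravy(seq: str) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle value per residue."""
    _check_seq(seq)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def instability_index(seq: str) -> float:
    """Instability index: (10/L) x sum of dipeptide instability weights (DIWV).

    Values above 40 predict an unstable protein in vitro.
    """
    _check_seq(seq, min_len=2)
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        total += DIWV[a][b]
    return 10.0 / len(seq) * total


def aliphatic_index(seq: str) -> float:
    """Aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), X in mole percent."""
    _check_seq(seq)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


# ---------------------------------------------------------------------------
# Profiles and family summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyschemProfile:
    """The five descriptors (plus length) for one protein."""

    id: str
    length: int
    mw: float
    pi: float
    instability: float
    aliphatic: float
    gravy: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.id}: length must be >= 1")
        if self.mw <= 0:
            raise ValueError(f"{self.id}: MW must be > 0")
        if not (0 < self.pi < 14):
            raise ValueError(f"{self.id}: pI must be in (0, 14)")
        if self.aliphatic < 0:
            raise ValueError(f"{self.id}: aliphatic index must be >= 0")


def profile(record: ProteinRecord) -> PhyschemProfile:
    """Compute the full descriptor profile for one protein."""
    seq = record.seq
    return PhyschemProfile(
        id=record.id,
        length=len(seq),
        mw=molecular_weight(seq),
        pi=theoretical_pi(seq),
        instability=instability_index(seq),
        aliphatic=aliphatic_index(seq),
        gravy=gravy(seq),
    )


def profile_all(records: Iterable[ProteinRecord]) -> list[PhyschemProfile]:
    return [profile(r) for r in records]


@dataclass(frozen=True)
class FamilySummary:
    """Family-level summary of descriptor profiles.

    Rounding matches reporting precision: mean MW to 0.1 kDa, pI values to
    0.01, percentages to 0.1.
    """

    n_proteins: int
    mean_mw_kda: float
    mean_pi: float
    pct_pi_above: float
    pi_threshold: float
    group_mean_pi: dict[str, float]
    n_gravy_positive: int
    gravy_positive_groups: tuple[str, ...]
    n_mw_above_kda: int
    mw_threshold_kda: float
    min_pi: tuple[str, float]
    max_pi: tuple[str, float]
    min_mw: tuple[str, float]
    max_mw: tuple[str, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_pi_above <= 100.0):
            raise ValueError("percentage out of [0, 100]")


def summarize_profiles(
    profiles: Sequence[PhyschemProfile],
    groups: Mapping[str, str],
    *,
    pi_threshold: float = 7.0,
    mw_threshold_kda: float = 30.0,
) -> FamilySummary:
    """Summary statistics over a family of descriptor profiles.

    Parameters
    ----------
    profiles:
        One profile per family member.
    groups:
        Mapping from protein id to group label (must cover every profile and
        use only known group names).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles:
        if p.id not in groups:
            raise ValueError(f"no group label for {p.id!r}")
        if groups[p.id] not in GROUPS:
            raise ValueError(f"unknown group label {groups[p.id]!r} for {p.id!r}")

    n = len(profiles)
    mws = np.array([p.mw for p in profiles])
    pis = np.array([p.pi for p in profiles])
    gravys = np.array([p.gravy for p in profiles])

    by_group: dict[str, list[float]] = {}
    for p in profiles:
        by_group.setdefault(groups[p.id], []).append(p.pi)
    group_mean_pi = {g: round(float(np.mean(v)), 2) for g, v in sorted(by_group.items())}

    gravy_pos = [p for p in profiles if p.gravy > 0]
    mw_above = [p for p in profiles if p.mw / 1000.0 > mw_threshold_kda]
    i_min_pi, i_max_pi = int(np.argmin(pis)), int(np.argmax(pis))
    i_min_mw, i_max_mw = int(np.argmin(mws)), int(np.argmax(mws))

    return FamilySummary(
        n_proteins=n,
        mean_mw_kda=round(float(mws.mean()) / 1000.0, 1),
        mean_pi=round(float(pis.mean()), 2),
        pct_pi_above=round(100.0 * float((pis > pi_threshold).sum()) / n, 1),
        pi_threshold=pi_threshold,
        group_mean_pi=group_mean_pi,
        n_gravy_positive=len(gravy_pos),
        gravy_positive_groups=tuple(sorted({groups[p.id] for p in gravy_pos})),
        n_mw_above_kda=len(mw_above),
        mw_threshold_kda=mw_threshold_kda,
        min_pi=(profiles[i_min_pi].id, round(float(pis[i_min_pi]), 2)),
        max_pi=(profiles[i_max_pi].id, round(float(pis[i_max_pi]), 2)),
        min_mw=(profiles[i_min_mw].id, round(float(mws[i_min_mw]), 2)),
        max_mw=(profiles[i_max_mw].id, round(float(mws[i_max_mw]), 2)),
    )


def validate_against_table(
    profiles: Sequence[PhyschemProfile],
    table: Mapping[str, Mapping[str, float]],
) -> tuple[float, list[tuple[str, str, float, float]]]:
    """Compare computed profiles with a published descriptor table.

    ``table`` maps protein id to ``{column: printed value}`` with columns among
    ``length, mw, pi, instability, aliphatic, gravy``. Each cell is compared at
    its printed precision (MW/pI/indices to 0.01, GRAVY to 0.001, length exact).
    Returns the fraction of matching cells and the list of mismatches as
    ``(id, column, computed, printed)``.
    """
    precision = {"length": 0, "mw": 2, "pi": 2, "instability": 2, "aliphatic": 2, "gravy": 3}
    matched = 0
    total = 0
    mismatches: list[tuple[str, str, float, float]] = []
    by_id = {p.id: p for p in profiles}
    for pid, cells in table.items():
        p = by_id.get(pid)
        if p is None:
            raise ValueError(f"no computed profile for table entry {pid!r}")
        for col, printed in cells.items():
            if col not in precision:
                raise ValueError(f"unknown descriptor column {col!r}")
            computed = float(getattr(p, col))
            total += 1
            # a printed value is a rounding of the true one: match if the
            # computed value rounds to it at the printed precision
            if round(computed, precision[col]) == round(float(printed), precision[col]):
                matched += 1
            else:
                mismatches.append((pid, col, computed, float(printed)))
    if total == 0:
        raise ValueError("empty validation table")
    return matched / total, mismatches
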