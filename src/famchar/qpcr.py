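"""Relative qPCR quantification by the 2^-dCt method with replicate statistics.

dCt = Ct(target) - Ct(reference) per biological replicate; relative expression
is 2^-dCt. Replicates are paired target/reference by replicate index, relative
expression is computed per replicate first, and the mean and sample SD are
taken over those expression values (matching "mean +/- SD of replicates"
applied to plotted expression levels). No amplification-efficiency correction
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from famchar.core_io import CtRecord


@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    target_gene: str
    mean_rel: float
    sd_rel: float  # sample SD (0.0 when n == 1)
    n: int
    delta_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mean_rel <= 0:
            raise ValueError("mean relative expression must be > 0")
        if self.n < 1:
            raise ValueError("need >= 1 replicate")


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt = Ct(target) - Ct(reference)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return ct_target - ct_reference


def relative_expression(dct: float) -> float:
    """2^-dCt (strictly decreasing in dCt)."""
    if not np.isfinite(dct):
        raise ValueError("delta Ct must be finite")
    return 2.0 ** (-dct)


def replicate_stats(target: CtRecord, reference: CtRecord) -> RelativeExpression:
    """Mean and sample SD of per-replicate 2^-dCt for one sample/target.

    ``target`` and ``reference`` must come from the same sample and have the
    same replicate count (replicates are paired by index).
    """
    if target.sample != reference.sample:
        raise ValueError(
            f"sample mismatch: {target.sample!r} vs {reference.sample!r}"
        )
    if reference.target_gene != target.reference_gene:
        raise ValueError(
            f"{target.sample}: reference record is for {reference.target_gene!r}, "
            f"expected {target.reference_gene!r}"
        )
    if len(target.ct_replicates) != len(reference.ct_replicates):
        raise ValueError(
            f"{target.sample}/{target.target_gene}: replicate count mismatch "
            f"({len(target.ct_replicates)} target vs {len(reference.ct_replicates)} reference)"
        )
    dcts = tuple(
        delta_ct(ct_t, ct_r)
        for ct_t, ct_r in zip(target.ct_replicates, reference.ct_replicates)
    )
    rels = np.array([relative_expression(d) for d in dcts])
    sd = float(rels.std(ddof=1)) if len(rels) > 1 else 0.0
    return RelativeExpression(
        sample=target.sample,
        target_gene=target.target_gene,
        mean_rel=float(rels.mean()),
        sd_rel=sd,
        n=len(rels),
        delta_ct=dcts,
    )


def quantify_all(records: Iterable[CtRecord]) -> list[RelativeExpression]:
    """Relative expression for every non-reference (sample, target) record."""
    records = list(records)
    refs = {
        (r.sample, r.target_gene): r
        for r in records
        if r.target_gene == r.reference_gene
    }
    out = []
    for rec in records:
        if rec.target_gene == rec.reference_gene:
            continue
        ref = refs.get((rec.sample, rec.reference_gene))
        if ref is None:
            raise ValueError(
                f"sample {rec.sample!r}: no reference measurements for "
                f"{rec.reference_gene!r}"
            )
        out.append(replicate_stats(rec, ref))
    return out


def write_relative_expression(results: Iterable[RelativeExpression], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\ttarget_gene\tmean_rel\tsd_rel\tn\n")
        for r in results:
            fh.write(f"{r.sample}\t{r.target_gene}\t{r.mean_rel:.6g}\t{r.sd_rel:.6g}\t{r.n}\n")
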