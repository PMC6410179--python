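"""FPKM expression transforms: pseudocount, log2 fold change, sqrt display
transform, coefficient of variation, and induced/inhibited response calls.

Fold changes are log2(FPKM_treatment / FPKM_control) after a small pseudocount
(default 1e-5) is added to every cell so ratios stay finite for dropout genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from famchar.core_io import ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 0.00001
DEFAULT_FC_THRESHOLD = 1.0  # |log2 FC| >= 1, i.e. 2-fold


@dataclass(frozen=True)
class FoldChangeRecord:
    gene_id: str
    treatment: str
    control: str
    fc: float  # log2 ratio

    def __post_init__(self) -> None:
        if not np.isfinite(self.fc):
            raise ValueError(f"{self.gene_id}: fold change must be finite")


def add_pseudocount(matrix: ExpressionMatrix, eps: float = DEFAULT_PSEUDOCOUNT) -> ExpressionMatrix:
    """Add ``eps`` to every cell (a monotone shift: value order is preserved)."""
    if eps <= 0:
        raise ValueError(f"pseudocount must be > 0, got {eps}")
    return ExpressionMatrix(matrix.df + eps)


def log2_fold_change(
    matrix: ExpressionMatrix, treatment: str, control: str
) -> list[FoldChangeRecord]:
    """Per-gene log2(treatment / control); apply :func:`add_pseudocount` first."""
    for label in (treatment, control):
        if label not in matrix.conditions:
            raise ValueError(f"unknown condition label {label!r}")
    if (matrix.df[[treatment, control]].to_numpy() <= 0).any():
        raise ValueError("zero values present: add a pseudocount before fold changes")
    fc = np.log2(matrix.df[treatment] / matrix.df[control])
    return [
        FoldChangeRecord(gene_id=g, treatment=treatment, control=control, fc=float(v))
        for g, v in fc.items()
    ]


def sqrt_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise square root (the display transform for expression heights)."""
    return ExpressionMatrix(np.sqrt(matrix.df))


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: sample SD (n-1) / mean x 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean must be > 0 for a coefficient of variation")
    return float(arr.std(ddof=1) / mean * 100.0)


def cv_per_gene(matrix: ExpressionMatrix) -> dict[str, float]:
    """CV% of each gene across conditions (genes with zero mean are skipped)."""
    out = {}
    for gene in matrix.genes:
        row = matrix.df.loc[gene].to_numpy()
        if row.mean() > 0:
            out[gene] = cv_percent(row)
    return out


def call_response(fc: float, threshold: float = DEFAULT_FC_THRESHOLD) -> str:
    """Classify a log2 fold change as induced / inhibited / unchanged."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if fc >= threshold:
        return "induced"
    if fc <= -threshold:
        return "inhibited"
    return "unchanged"


def fold_change_table(
    matrix: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    *,
    eps: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Fold changes and response calls for a list of (treatment, control) pairs."""
    shifted = add_pseudocount(matrix, eps)
    rows = []
    for treatment, control in pairs:
        for rec in log2_fold_change(shifted, treatment, control):
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "treatment": rec.treatment,
                    "control": rec.control,
                    "log2_fc": rec.fc,
                    "response": call_response(rec.fc, threshold),
                }
            )
    return pd.DataFrame(rows)
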