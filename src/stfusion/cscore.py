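"""Per-spot C-scores for a candidate fusion gene pair.

The C-score compares, in every spot, the two parental genes of a
candidate fusion transcript through their spot-to-sample-mean
expression ratios

    R5' = expr5_s / mean(expr5)      R3' = expr3_s / mean(expr3)

and keeps the larger one, signed:

    C = -R5'  if R5' >= R3'   (5' gene dominates: fusion absent,
                               C mirrors the 5' gene expression)
    C = +R3'  otherwise       (3' gene dominates: fusion present,
                               C mirrors the fusion expression)

A fused transcript is captured by poly(A)-based ST only through the 3'
gene's tail, so the 5' gene of a fused spot loses signal while the 3'
gene gains the 5' promoter's output — a positive C-score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .types import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "gene_ratio",
    "cscore_value",
    "cscore_map",
    "label_spot",
    "grade_spot",
    "CScoreTable",
    "LABELS",
    "GRADES",
]

Convention = Literal["strict", "fig3"]
LABELS = ("absence", "neutral", "occurrence")
GRADES = (
    "strong_absence",
    "mild_absence",
    "mild_occurrence",
    "strong_occurrence",
)


@dataclass
class CScoreTable:
    """Per-spot C-scores for one gene pair of one (or more) sections.

    ``table`` columns: ``sample, r5, r3, cscore, label`` (and ``grade``
    when graded); index is the spot label.
    """

    gene5: str
    gene3: str
    table: pd.DataFrame
    convention: Convention = "strict"
    pseudocount: bool = False
    occ_threshold: float = 0.0

    @property
    def cscores(self) -> pd.Series:
        return self.table["cscore"]

    def spots_with_label(self, label: str) -> pd.Index:
        return self.table.index[self.table["label"] == label]


def gene_ratio(expr: np.ndarray | pd.Series, pseudocount: bool = False) -> np.ndarray:
    """Spot-to-sample-mean expression ratios for one gene.

    With ``pseudocount`` a count of 1 is added to dividend and divisor,
    so ratios of an unexpressed gene become 1 rather than 0. Without it
    an all-zero gene yields all-zero ratios (0/0 := 0, with a warning)
    so that a silenced 5' gene — the fusion signature — stays scorable.
    """
    x = np.asarray(expr, dtype=float)
    if x.size == 0:
        raise ValueError("gene_ratio needs at least one spot")
    if (x < 0).any():
        raise ValueError("negative expression value")
    mean = x.mean()
    if pseudocount:
        return (x + 1.0) / (mean + 1.0)
    if mean == 0:
        warnings.warn("all-zero gene: ratios defined as 0")
        return np.zeros_like(x)
    return x / mean


def cscore_value(r5: float, r3: float) -> float:
    """Signed C-score of one spot from its two ratios.

    The tie ``r5 == r3`` lands in the absence branch; the magnitude is
    always ``max(r5, r3)``.
    """
    if r5 < 0 or r3 < 0:
        raise ValueError("ratios must be non-negative")
    if r5 >= r3:
        return -r5 if r5 != 0 else 0.0
    return r3


def label_spot(
    cscore: float,
    convention: Convention = "strict",
    occ_threshold: float = 0.0,
) -> str:
    """Occurrence/absence label of a spot.

    ``strict``: C < 0 absence, C > occ_threshold occurrence, otherwise
    neutral (neutral spots are excluded from the DE groups).
    ``fig3``: every spot at or below the occurrence boundary is
    absence; there is no neutral class.

    ``occ_threshold`` shifts the occurrence boundary; it is mainly
    useful with pseudocounted ratios, which never reach exactly 0.
    """
    if convention == "strict":
        if cscore < 0:
            return "absence"
        if cscore > occ_threshold:
            return "occurrence"
        return "neutral"
    if convention == "fig3":
        return "occurrence" if cscore > occ_threshold else "absence"
    raise ValueError(f"unknown labelling convention {convention!r}")


def grade_spot(cscore: float, mild: float = 1.0) -> str:
    """Four-way grade of a C-score around the +-``mild`` thresholds.

    C <= -mild: strong absence; -mild < C <= 0: mild absence;
    0 < C < mild: mild occurrence; C >= mild: strong occurrence.
    """
    if mild <= 0:
        raise ValueError("mild threshold must be positive")
    if cscore <= -mild:
        return "strong_absence"
    if cscore <= 0:
        return "mild_absence"
    if cscore < mild:
        return "mild_occurrence"
    return "strong_occurrence"


def cscore_map(
    m: CountMatrix,
    pair: tuple[str, str],
    pseudocount: bool = False,
    convention: Convention = "strict",
    occ_threshold: float = 0.0,
    mild: float = 1.0,
) -> CScoreTable:
    """C-scores of every spot of one section for a 5'/3' gene pair.

    Ratios are taken against the section's own mean expression
    (per-sample means), so multi-section analyses score each section
    separately before concatenating.
    """
    gene5, gene3 = pair
    for g in (gene5, gene3):
        if g not in m.counts.columns:
            raise KeyError(f"gene {g!r} not present in count matrix")
    r5 = gene_ratio(m.counts[gene5], pseudocount=pseudocount)
    r3 = gene_ratio(m.counts[gene3], pseudocount=pseudocount)
    cs = np.where(r5 >= r3, -r5, r3)
    cs[cs == 0] = 0.0  # collapse signed zero
    labels = [label_spot(c, convention, occ_threshold) for c in cs]
    grades = [grade_spot(c, mild) for c in cs]
    table = pd.DataFrame(
        {
            "sample": m.sample,
            "r5": r5,
            "r3": r3,
            "cscore": cs,
            "label": labels,
            "grade": grades,
        },
        index=m.counts.index,
    )
    return CScoreTable(
        gene5=gene5,
        gene3=gene3,
        table=table,
        convention=convention,
        pseudocount=pseudocount,
        occ_threshold=occ_threshold,
    )


def write_cscore_table(cs: CScoreTable, path) -> None:
    cs.table.to_csv(path, sep="\t", index_label="spot")


def read_cscore_table(path, gene5: str = "gene5", gene3: str = "gene3") -> CScoreTable:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return CScoreTable(gene5=gene5, gene3=gene3, table=table)
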