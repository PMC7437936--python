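"""Mechanism calls for gene pairs from per-gene poly(A)-tail counts.

A chimeric transcript produced by read-through transcription (cis-SAGe)
or by a genomic gene fusion carries a single poly(A) tail, attached
downstream of the 3' parental gene: tails effectively vanish from the
5' gene while the 3' gene's tail count is driven by the 5' promoter.
A trans-splicing chimera instead joins two independently transcribed,
independently polyadenylated mRNAs, so both parental genes keep tails.
The classifier turns the two tail counts of a pair into one of three
calls; it cannot tell cis-SAGe apart from a genomic fusion (both
silence the 5' tail), which is why the call is named ``fusion_pattern``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = ["classify_polya", "classify_table", "PolyAProfile", "CALLS"]

CALLS = ("fusion_pattern", "trans_splicing_pattern", "undetected")


@dataclass(frozen=True)
class PolyAProfile:
    """Tail counts of one pair's parental genes plus the mechanism call."""

    gene5: str
    gene3: str
    count5: int
    count3: int
    call: str


def classify_polya(count5: int, count3: int, zero_tol: int = 0) -> str:
    """Mechanism call from the 5' and 3' parental-gene tail counts.

    ``zero_tol`` is the largest count still treated as "no tail"
    (default 0, strict absence; raise it when sequencing noise produces
    spurious single tails).

    Returns ``fusion_pattern`` (5' silent, 3' expressed: cis-SAGe or
    gene fusion), ``trans_splicing_pattern`` (both expressed; also
    matches plain unfused co-expression), or ``undetected`` (both
    silent).
    """
    if count5 < 0 or count3 < 0:
        raise ValueError("poly(A)-tail counts must be non-negative")
    if zero_tol < 0:
        raise ValueError("zero_tol must be non-negative")
    if count3 > zero_tol:
        return "fusion_pattern" if count5 <= zero_tol else "trans_splicing_pattern"
    # no 3' tail: no chimera evidence either way, whatever the 5' count
    return "undetected"


def classify_table(
    pairs: Sequence[tuple[str, str]],
    tail_counts: Mapping[str, int],
    zero_tol: int = 0,
) -> list[PolyAProfile]:
    """Classify every pair against a gene -> tail-count table.

    Genes absent from the table are treated as count 0 (no tail
    observed). Per-call totals are logged.
    """
    out = []
    for gene5, gene3 in pairs:
        c5 = int(tail_counts.get(gene5, 0))
        c3 = int(tail_counts.get(gene3, 0))
        out.append(
            PolyAProfile(
                gene5=gene5,
                gene3=gene3,
                count5=c5,
                count3=c3,
                call=classify_polya(c5, c3, zero_tol=zero_tol),
            )
        )
    tally: dict[str, int] = {}
    for p in out:
        tally[p.call] = tally.get(p.call, 0) + 1
    logger.info("poly(A) classification: %s", tally)
    return out
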