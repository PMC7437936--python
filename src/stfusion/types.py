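"""Core in-memory containers shared across the package.

Spatial-transcriptomics (ST) arrays index their capture spots by 1-based
array coordinates, conventionally printed as ``"10x12"`` (column x row).
A :class:`CountMatrix` holds the raw unique-molecule counts of one tissue
section (spots x genes); derived real-valued matrices (normalized
expression, C-scores, factor activities) live in separate containers so
that raw integer counts are never silently overwritten.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SpotId",
    "CountMatrix",
    "FactorActivityMap",
    "NormalizedMatrix",
    "GeneAnnotationRecord",
    "parse_spot_id",
    "format_spot_id",
]

_SPOT_RE = re.compile(r"^\s*(\d+)\s*[x×]\s*(\d+)\s*$")


class SpotId(NamedTuple):
    """One capture spot: tissue-section label plus 1-based array coordinates."""

    sample: str
    x: int  # array column
    y: int  # array row

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.x}x{self.y}"


def parse_spot_id(token: str, sample: str = "sample") -> SpotId:
    """Parse an ``"NxM"`` spot label (``x`` or ``×`` separator) into a SpotId.

    Raises
    ------
    ValueError
        If the token has no separator, non-integer parts, or coordinates
        below 1 (the ST convention is 1-based).
    """
    m = _SPOT_RE.match(str(token))
    if m is None:
        raise ValueError(
            f"malformed spot ID {token!r}: expected 'NxM' with integer "
            "column and row separated by 'x'"
        )
    x, y = int(m.group(1)), int(m.group(2))
    if x < 1 or y < 1:
        raise ValueError(f"malformed spot ID {token!r}: coordinates are 1-based")
    return SpotId(sample, x, y)


def format_spot_id(spot: SpotId) -> str:
    return f"{spot.x}x{spot.y}"


def _check_spot_index(index: Iterable[str], sample: str) -> list[SpotId]:
    spots = [parse_spot_id(tok, sample) for tok in index]
    if len(spots) == 0:
        raise ValueError("no spots")
    if len(set(spots)) != len(spots):
        raise ValueError("duplicate spot IDs within one sample")
    return spots


@dataclass
class CountMatrix:
    """Raw spot x gene counts of one tissue section.

    Parameters
    ----------
    counts
        DataFrame with spot labels (``"NxM"``) as index, gene symbols as
        columns, and non-negative integer entries.
    sample
        Label of the tissue section (e.g. ``"2.4"``); becomes the
        ``sample`` field of every :class:`SpotId`.
    """

    counts: pd.DataFrame
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValueError("no spots")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbol(s): {sorted(set(dupes))}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            # accept float frames that are exactly integral (e.g. from TSV)
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            spot_i, gene_i = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at spot {self.counts.index[spot_i]!r}, "
                f"gene {self.counts.columns[gene_i]!r}"
            )
        _check_spot_index(self.counts.index, self.sample)

    @property
    def spot_ids(self) -> list[SpotId]:
        return [parse_spot_id(tok, self.sample) for tok in self.counts.index]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    def library_sizes(self) -> pd.Series:
        """Total counts per spot."""
        return self.counts.sum(axis=1)

    def coordinates(self) -> pd.DataFrame:
        """Per-spot (x, y) array coordinates as a DataFrame."""
        ids = self.spot_ids
        return pd.DataFrame(
            {"x": [s.x for s in ids], "y": [s.y for s in ids]},
            index=self.counts.index,
        )


@dataclass
class FactorActivityMap:
    """Per-spot activities of transcriptomic factors, each in [0, 1].

    A factor is an expression profile inferred by factor decomposition of
    ST data (e.g. "Cancer", "PIN glands", "Normal glands"); its activity
    says where in the section the profile is active.
    """

    activity: pd.DataFrame  # spots x factors
    sample: str = "sample"

    def __post_init__(self) -> None:
        vals = self.activity.to_numpy(dtype=float)
        if vals.size and ((vals < 0) | (vals > 1)).any():
            bad = np.argwhere((vals < 0) | (vals > 1))[0]
            raise ValueError(
                "factor activity outside [0, 1] at spot "
                f"{self.activity.index[bad[0]]!r}, factor "
                f"{self.activity.columns[bad[1]]!r}"
            )
        _check_spot_index(self.activity.index, self.sample)

    @property
    def factors(self) -> list[str]:
        return list(self.activity.columns)


@dataclass
class NormalizedMatrix:
    """Normalized expression values plus the per-spot size factors used.

    ``values = counts / size_factor`` per spot; size factors are positive
    and average to 1 over the section so normalized values stay on the
    scale of the raw counts.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    sample: str = "sample"

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if abs(float(self.size_factors.mean()) - 1.0) > 1e-9:
            raise ValueError("size factors must average to 1")
        if not self.values.index.equals(self.size_factors.index):
            raise ValueError("values and size_factors disagree on spots")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """One gene locus: 1-based inclusive coordinates plus strand."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene!r}: strand must be '+' or '-'")
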