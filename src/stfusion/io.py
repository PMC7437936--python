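"""Readers and writers for the on-disk formats the pipeline consumes.

All tabular formats are tab-separated UTF-8 with a header row. Count
matrices follow the public ST dataset dialect: spot labels ``"NxM"``
(column x row, 1-based) on one axis and gene symbols on the other;
orientation is auto-detected from which header parses as spot IDs.
Gene annotation is read from GTF/GFF3 via :mod:`gffutils`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .types import (
    CountMatrix,
    FactorActivityMap,
    GeneAnnotationRecord,
    parse_spot_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_factor_activity",
    "write_factor_activity",
    "read_polya_table",
    "write_polya_table",
    "read_annotation",
]

Orientation = Literal["auto", "spots_as_rows", "spots_as_columns"]


def _is_spot_header(tokens) -> bool:
    if len(tokens) == 0:
        return False
    for tok in tokens:
        try:
            parse_spot_id(tok)
        except ValueError:
            return False
    return True


def read_count_matrix(
    path: str | Path,
    sample: str | None = None,
    orientation: Orientation = "auto",
) -> CountMatrix:
    """Read a spots x genes count matrix from TSV.

    The file may have spots as columns and genes as rows (the published
    ST layout) or the transpose; with ``orientation="auto"`` the layout
    is detected from which header consists of ``"NxM"`` spot labels.

    Parameters
    ----------
    path
        TSV file with a header row and a leading label column.
    sample
        Tissue-section label; defaults to the file stem.
    orientation
        ``"spots_as_rows"``/``"spots_as_columns"`` force the layout.

    Raises
    ------
    ValueError
        Empty file, malformed spot IDs, duplicate genes, or negative /
        non-integer cells.
    """
    path = Path(path)
    if sample is None:
        sample = path.stem
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no spots (empty file)") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no spots")

    if orientation == "auto":
        cols_are_spots = _is_spot_header(df.columns)
        rows_are_spots = _is_spot_header(df.index)
        if cols_are_spots and not rows_are_spots:
            df = df.T
        elif rows_are_spots and not cols_are_spots:
            pass
        elif cols_are_spots and rows_are_spots:
            raise ValueError(
                f"{path}: both axes parse as spot IDs; force orientation"
            )
        else:
            raise ValueError(
                f"{path}: neither header parses as 'NxM' spot IDs"
            )
    elif orientation == "spots_as_columns":
        df = df.T
    # spots now on rows, genes on columns
    for spot in df.index:
        parse_spot_id(spot)  # raises with the offending token
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(t, np.number) for t in df.dtypes]
        ].tolist()
        raise ValueError(f"{path}: non-numeric counts in column(s) {bad}")
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative count at spot {df.index[i]!r}, gene "
            f"{df.columns[j]!r}"
        )
    if np.any(arr != np.floor(arr)):
        i, j = np.argwhere(arr != np.floor(arr))[0]
        raise ValueError(
            f"{path}: non-integer count at spot {df.index[i]!r}, gene "
            f"{df.columns[j]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return CountMatrix(counts=df.astype(np.int64), sample=sample)


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as spots-as-rows TSV (round-trips exactly)."""
    m.counts.to_csv(path, sep="\t", index_label="spot")


def read_factor_activity(
    path: str | Path,
    sample: str | None = None,
    rescale: bool = False,
) -> FactorActivityMap:
    """Read a spots x factors activity table from TSV.

    Activities must lie in [0, 1]; with ``rescale=True`` each factor is
    min-max rescaled onto [0, 1] instead (constant factors are rejected
    as degenerate).
    """
    path = Path(path)
    if sample is None:
        sample = path.stem
    df = pd.read_csv(path, sep="\t", index_col=0)
    for spot in df.index:
        parse_spot_id(spot)
    df = df.astype(float)
    if rescale:
        lo, hi = df.min(axis=0), df.max(axis=0)
        flat = df.columns[(hi - lo) <= 0]
        if len(flat):
            raise ValueError(
                f"degenerate factor(s) {flat.tolist()}: min = max, cannot rescale"
            )
        df = (df - lo) / (hi - lo)
    df.index = df.index.astype(str)
    return FactorActivityMap(activity=df, sample=sample)


def write_factor_activity(fa: FactorActivityMap, path: str | Path) -> None:
    fa.activity.to_csv(path, sep="\t", index_label="spot")


def read_polya_table(path: str | Path) -> dict[str, int]:
    """Read a two-column ``gene<TAB>count`` poly(A)-tail table.

    Returns a mapping from gene symbol to the number of poly(A) tails
    observed for that gene (e.g. from TAIL-seq). Counts must be
    non-negative integers; an empty table yields an empty mapping.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns gene<TAB>count")
    if df.shape[0] == 0:
        return {}
    genes = df.iloc[:, 0].astype(str)
    counts = df.iloc[:, 1]
    if np.any(counts != np.floor(counts)):
        raise ValueError(f"{path}: non-integer poly(A) count")
    counts = counts.astype(int)
    if (counts < 0).any():
        gene = genes[counts.lt(0)].iloc[0]
        raise ValueError(f"{path}: negative poly(A) count for gene {gene!r}")
    return dict(zip(genes, counts))


def write_polya_table(table: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(table.keys()), "count": list(table.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[GeneAnnotationRecord]:
    """Read gene loci from a GTF/GFF3 file.

    One record per gene, 1-based inclusive coordinates. ``gene``
    features are used directly; if the file carries only sub-gene
    features (e.g. exons) the gene span is inferred as the min/max
    extent of its features. Features without a strand are skipped with
    a warning; ``end < start`` raises.
    """
    spans: dict[str, dict] = {}
    have_gene_feature: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype not in {
                "gene", "exon", "transcript", "mRNA", "CDS",
            }:
                continue
            name = (
                feat.attributes.get("gene_name")
                or feat.attributes.get("gene_id")
                or feat.attributes.get("Name")
                or feat.attributes.get("ID")
            )
            if not name:
                warnings.warn(f"feature without gene identifier skipped: {line!r}")
                continue
            name = name[0]
            if feat.strand not in {"+", "-"}:
                warnings.warn(f"gene {name!r}: missing strand, record skipped")
                continue
            if feat.end < feat.start:
                raise ValueError(
                    f"gene {name!r}: end ({feat.end}) < start ({feat.start})"
                )
            is_gene = feat.featuretype == "gene"
            rec = spans.get(name)
            if rec is None:
                spans[name] = {
                    "chrom": feat.seqid,
                    "start": feat.start,
                    "end": feat.end,
                    "strand": feat.strand,
                }
            elif is_gene or name not in have_gene_feature:
                rec["start"] = min(rec["start"], feat.start)
                rec["end"] = max(rec["end"], feat.end)
            if is_gene:
                have_gene_feature.add(name)
    return [
        GeneAnnotationRecord(gene=g, **v) for g, v in spans.items()
    ]
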