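"""Occurrence-vs-absence differential expression.

Spots are grouped purely by their C-score sign (strict convention:
C < 0 absence, C > 0 occurrence, C = 0 excluded) — no tissue
annotation enters. Per gene, the fold change is the ratio of normalized
group means, significance comes from a two-sample t-test (Welch by
default), and p-values are Benjamini-Hochberg adjusted. The final
export is a plain gene list for external pathway-enrichment services.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cscore import CScoreTable
from .types import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "split_groups",
    "de_test",
    "bh_adjust",
    "significant_genes",
    "DEResult",
]


@dataclass
class DEResult:
    gene: str
    mean_occ: float
    mean_abs: float
    fold_change: float  # mean_occ / mean_abs; +inf when mean_abs == 0
    t_stat: float
    p_value: float
    q_value: float = math.nan
    significant: bool = False


def split_groups(cs: CScoreTable) -> tuple[pd.Index, pd.Index]:
    """(occurrence spots, absence spots) under the strict convention.

    Spots with C-score exactly 0 belong to neither group. Each group
    must contain at least 2 spots for the t-test to be defined.
    """
    c = cs.cscores
    occurrence = c.index[c > 0]
    absence = c.index[c < 0]
    if len(occurrence) == 0:
        raise ValueError("occurrence group empty")
    if len(absence) == 0:
        raise ValueError("absence group empty")
    if len(occurrence) < 2 or len(absence) < 2:
        raise ValueError(
            "both groups need >= 2 spots for a t-test "
            f"(occurrence {len(occurrence)}, absence {len(absence)})"
        )
    return occurrence, absence


def de_test(
    nm: NormalizedMatrix,
    groups: tuple[pd.Index, pd.Index],
    variant: Literal["welch", "pooled"] = "welch",
) -> list[DEResult]:
    """Per-gene two-sample t-test between occurrence and absence spots.

    ``welch`` (default) does not assume equal group variances;
    ``pooled`` is the classical equal-variance test. Genes with zero
    variance in both groups and equal means get t = 0, p = 1.
    """
    occ_idx, abs_idx = groups
    occ = nm.values.loc[occ_idx].to_numpy(dtype=float)
    ab = nm.values.loc[abs_idx].to_numpy(dtype=float)
    if occ.shape[0] < 2 or ab.shape[0] < 2:
        raise ValueError("both groups need >= 2 spots")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(occ, ab, equal_var=(variant == "pooled"), axis=0)
    mean_occ = occ.mean(axis=0)
    mean_abs = ab.mean(axis=0)
    # zero variance in both groups with equal means -> nan from scipy;
    # defined here as t = 0, p = 1 (no evidence either way)
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_abs > 0, mean_occ / np.where(mean_abs > 0, mean_abs, 1.0), np.inf)
    fc = np.where((mean_abs == 0) & (mean_occ == 0), np.nan, fc)
    return [
        DEResult(
            gene=g,
            mean_occ=float(mo),
            mean_abs=float(ma),
            fold_change=float(f),
            t_stat=float(ti),
            p_value=float(pi),
        )
        for g, mo, ma, f, ti, pi in zip(nm.genes, mean_occ, mean_abs, fc, t, p)
    ]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_q(results: list[DEResult], q_cut: float = 0.1) -> list[DEResult]:
    """Fill in q-values and significance flags in place."""
    if not results:
        return results
    q = bh_adjust([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
        r.significant = bool(qi < q_cut)
    return results


def significant_genes(results: list[DEResult], q_cut: float = 0.1) -> list[str]:
    """Genes with q < ``q_cut``, ordered by q then |log fold change|.

    The list is what an external pathway-enrichment service (e.g. a
    KEGG-based web tool) takes as input; enrichment itself is not done
    here.
    """
    if not results:
        return []
    if any(math.isnan(r.q_value) for r in results):
        annotate_q(results, q_cut)

    def log_fc_mag(r: DEResult) -> float:
        if not math.isfinite(r.fold_change) or r.fold_change <= 0:
            return math.inf
        return abs(math.log(r.fold_change))

    hits = [r for r in results if r.q_value < q_cut]
    hits.sort(key=lambda r: (r.q_value, -log_fc_mag(r), r.gene))
    return [r.gene for r in hits]


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "mean_occurrence": [r.mean_occ for r in results],
            "mean_absence": [r.mean_abs for r in results],
            "fold_change": [r.fold_change for r in results],
            "t": [r.t_stat for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("gene")
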