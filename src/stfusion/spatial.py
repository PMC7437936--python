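"""Relating C-score maps to transcriptomic-factor activity maps.

Two summaries connect the per-spot fusion signal to tissue biology:
correlation of the C-score with a factor's activity over all shared
spots of a section (is the fusion where the cancer is?), and the
fraction of factor-active spots in each C-score grade (how much of the
cancer area shows the fusion?). A diverging spatial rendering of the
C-score map mirrors the activity-map style of ST analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cscore import CScoreTable, GRADES, grade_spot
from .types import FactorActivityMap

logger = logging.getLogger(__name__)

__all__ = ["correlate_factor", "spot_fractions", "render_map",
           "FactorCorrelation", "FractionSummary"]


@dataclass(frozen=True)
class FactorCorrelation:
    sample: str
    factor: str
    n_spots: int
    rho_spearman: float
    rho_pearson: float
    p_spearman: float
    p_pearson: float


@dataclass(frozen=True)
class FractionSummary:
    factor: str
    activity_threshold: float
    n_spots: int
    fractions: dict  # grade -> fraction of selected spots


def correlate_factor(
    cs: CScoreTable, fa: FactorActivityMap, factor: str
) -> FactorCorrelation:
    """Pearson and Spearman correlation of C-score with factor activity.

    Uses every spot carrying both a C-score and an activity value
    (section-wide, not just factor-active spots). Spearman uses average
    ranks for ties; both p-values come from the two-sided
    t-approximation. Constant inputs make the correlation undefined and
    raise.
    """
    if factor not in fa.activity.columns:
        raise KeyError(f"factor {factor!r} not in activity map")
    shared = cs.table.index.intersection(fa.activity.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared spots to correlate")
    x = cs.table.loc[shared, "cscore"].to_numpy(dtype=float)
    y = fa.activity.loc[shared, factor].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"correlation undefined: constant "
            f"{'C-score' if np.ptp(x) == 0 else 'activity'} over shared spots"
        )
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return FactorCorrelation(
        sample=cs.table["sample"].iloc[0] if "sample" in cs.table else "",
        factor=factor,
        n_spots=int(len(shared)),
        rho_spearman=float(spearman.statistic),
        rho_pearson=float(pearson.statistic),
        p_spearman=float(spearman.pvalue),
        p_pearson=float(pearson.pvalue),
    )


def spot_fractions(
    cs: CScoreTable,
    fa: FactorActivityMap,
    factor: str,
    activity_threshold: float = 0.2,
    mild: float = 1.0,
) -> FractionSummary:
    """Grade fractions among the spots where a factor is active.

    Restricts to spots with activity strictly above
    ``activity_threshold`` (a proportion on [0, 1]; the conventional
    cut is 20%), grades each spot's C-score around +-``mild`` with
    C <= 0 counting as absence, and reports the fraction of selected
    spots per grade (fractions sum to 1).
    """
    if factor not in fa.activity.columns:
        raise KeyError(f"factor {factor!r} not in activity map")
    shared = cs.table.index.intersection(fa.activity.index)
    active = shared[fa.activity.loc[shared, factor] > activity_threshold]
    if len(active) == 0:
        raise ValueError(
            f"no spot has {factor!r} activity above {activity_threshold}"
        )
    grades = [grade_spot(c, mild) for c in cs.table.loc[active, "cscore"]]
    counts = {g: 0 for g in GRADES}
    for g in grades:
        counts[g] += 1
    n = len(active)
    return FractionSummary(
        factor=factor,
        activity_threshold=activity_threshold,
        n_spots=n,
        fractions={g: counts[g] / n for g in GRADES},
    )


def render_map(cs: CScoreTable, out: str, title: str | None = None):
    """Render the spatial C-score map as a diverging scatter plot.

    One marker per spot at its array coordinates, colour-coded with a
    diverging scale centred at 0 (blue = absence, red = occurrence).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cs.table.shape[0] == 0:
        raise ValueError("empty C-score table, nothing to render")
    from .types import parse_spot_id

    xs, ys = zip(*((s.x, s.y) for s in (parse_spot_id(t) for t in cs.table.index)))
    c = cs.table["cscore"].to_numpy(dtype=float)
    lim = max(1.0, float(np.abs(c).max()))
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(xs, ys, c=c, cmap="RdBu_r", vmin=-lim, vmax=lim, s=30)
    ax.invert_yaxis()  # array row 1 at the top, as sections are printed
    ax.set_xlabel("array column")
    ax.set_ylabel("array row")
    ax.set_title(title or f"{cs.gene5}-{cs.gene3} C-score")
    fig.colorbar(sc, ax=ax, label="C-score")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
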