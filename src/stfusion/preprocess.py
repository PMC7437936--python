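"""Spot QC, gene filtering, normalization and the variability filter.

These steps prepare a count matrix for the occurrence-vs-absence
differential-expression comparison. Spot-to-sample-mean C-scores are
deliberately computed on the *unfiltered* matrix, so this module sits
only on the DE branch of the pipeline.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .types import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["qc_spots", "filter_genes", "normalize", "sd_filter"]


def qc_spots(m: CountMatrix, n_mads: float = 3.0) -> CountMatrix:
    """Remove spots whose log-library size falls far below the median.

    A spot is kept when ``log(library size) >= median - n_mads * MAD``,
    where the MAD is the raw median absolute deviation of the natural
    log-library sizes (no normal-consistency scaling). Spots with zero
    total counts are always removed (their log-library size is
    undefined) with a warning.
    """
    if n_mads <= 0:
        raise ValueError("n_mads must be positive")
    lib = m.library_sizes()
    zero = lib.index[lib == 0]
    if len(zero):
        warnings.warn(
            f"{len(zero)} spot(s) with zero library size removed: "
            f"{zero.tolist()[:5]}"
        )
        lib = lib[lib > 0]
        if lib.empty:
            raise ValueError("all spots have zero library size")
    loglib = np.log(lib.to_numpy(dtype=float))
    med = float(np.median(loglib))
    mad = float(np.median(np.abs(loglib - med)))
    if math.isinf(n_mads):
        keep = lib.index
    else:
        keep = lib.index[loglib >= med - n_mads * mad]
    return CountMatrix(counts=m.counts.loc[keep].copy(), sample=m.sample)


def filter_genes(
    m: CountMatrix, min_total: int = 5, min_detected_spots: int = 3
) -> CountMatrix:
    """Drop low-abundance genes.

    Keeps genes whose total count is at least ``min_total`` and that are
    detected (count > 0) in at least ``min_detected_spots`` spots.
    """
    totals = m.counts.sum(axis=0)
    detected = (m.counts > 0).sum(axis=0)
    keep = m.counts.columns[(totals >= min_total) & (detected >= min_detected_spots)]
    if len(keep) == 0:
        raise ValueError("no genes survive filtering")
    return CountMatrix(counts=m.counts[keep].copy(), sample=m.sample)


def _pooled_size_factors(
    counts: np.ndarray, pool_sizes: Iterable[int]
) -> np.ndarray:
    """Simplified pooled-deconvolution size factors.

    Spots are ordered on a ring by library size; for each pool size a
    sliding window of spots is summed and the pool's size factor is
    estimated as the median ratio of the pooled profile to the average
    spot profile. The per-spot factors solve the resulting linear
    system by least squares, with a weak ridge toward library-size
    factors to keep the system well conditioned.
    """
    n = counts.shape[0]
    lib = counts.sum(axis=1).astype(float)
    ref = counts.mean(axis=0)
    expressed = ref > 0
    ref = ref[expressed]
    sub = counts[:, expressed].astype(float)
    order = np.argsort(lib, kind="stable")
    # alternate low/high to mix library sizes around the ring, as the
    # deconvolution approach prescribes
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2:][::-1]

    rows, cols, data, b = [], [], [], []
    eq = 0
    for size in pool_sizes:
        for start in range(n):
            members = ring[(start + np.arange(size)) % n]
            pooled = sub[members].sum(axis=0)
            theta = float(np.median(pooled / ref))
            for mi in members:
                rows.append(eq)
                cols.append(mi)
                data.append(1.0)
            b.append(theta)
            eq += 1
    lib_sf = lib / lib.mean()
    lam = math.sqrt(0.1)
    for i in range(n):
        rows.append(eq)
        cols.append(i)
        data.append(lam)
        b.append(lam * lib_sf[i])
        eq += 1
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import lsqr

    A = coo_matrix((data, (rows, cols)), shape=(eq, n)).tocsr()
    sol = lsqr(A, np.asarray(b), atol=1e-10, btol=1e-10)[0]
    sol = np.where(sol <= 0, lib_sf * 1e-3, sol)  # guard pathological fits
    return sol / sol.mean()


def normalize(
    m: CountMatrix,
    method: Literal["library_size", "pooled"] = "library_size",
    pool_sizes: tuple[int, ...] = (21, 41, 61),
) -> NormalizedMatrix:
    """Compute per-spot size factors and normalized expression values.

    ``library_size``: ``sf_s = lib_s / mean(lib)``. ``pooled``: a
    simplified pooled-deconvolution estimate (see
    :func:`_pooled_size_factors`); falls back to library-size factors
    with a warning when the section has fewer spots than the smallest
    pool. Size factors average to 1 either way, and
    ``values = counts / sf`` per spot.
    """
    lib = m.library_sizes().to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("every spot must have library size > 0; run qc_spots first")
    if method == "library_size":
        sf = lib / lib.mean()
    elif method == "pooled":
        sizes = [min(s, m.n_spots) for s in pool_sizes]
        if m.n_spots < min(pool_sizes):
            warnings.warn(
                f"{m.n_spots} spots < smallest pool size {min(pool_sizes)}; "
                "falling back to library-size factors"
            )
            sf = lib / lib.mean()
        else:
            sf = _pooled_size_factors(m.counts.to_numpy(), sizes)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    sf = pd.Series(sf, index=m.counts.index, name="size_factor")
    sf = sf / sf.mean()  # enforce mean 1 to tolerance
    values = m.counts.div(sf, axis=0)
    return NormalizedMatrix(values=values, size_factors=sf, sample=m.sample)


def sd_filter(
    nm: NormalizedMatrix,
    spots: Iterable[str] | None = None,
    frac: float = 0.1,
) -> list[str]:
    """Keep genes whose variability is not negligible over chosen spots.

    A gene passes when its sample standard deviation over the selected
    spots is at least ``frac`` times its mean there; genes with zero
    mean are removed. Returns the surviving gene symbols.
    """
    if frac < 0:
        raise ValueError("frac must be non-negative")
    values = nm.values if spots is None else nm.values.loc[list(spots)]
    if values.shape[0] < 2:
        raise ValueError("sd filter needs at least 2 spots (sd undefined)")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    keep = values.columns[(mean > 0) & (sd >= frac * mean)]
    return list(keep)
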