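"""Spatial structure of single-CpG methylation in PMDs.

Two readouts: the distance-dependent Pearson correlation of consecutive
CpGs (at exact base-pair distances, no pooling), and the per-domain
cross-sample correlation of single-CpG levels between two methylomes
restricted to their common PMDs.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .regions import RegionSet

log = logging.getLogger(__name__)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def distance_correlation(
    cpgs: pd.DataFrame,
    max_dist: int = 300,
    min_pairs: int = 50,
) -> pd.DataFrame:
    """Correlation of consecutive-CpG levels at each exact distance.

    Pairs are consecutive CpGs on the same chromosome; distance is the
    difference of their C positions.  Distances above ``max_dist`` or with
    fewer than ``min_pairs`` pairs are omitted.
    """
    xs, ys, ds = [], [], []
    for _, sub in cpgs.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        lev = sub["level"].to_numpy()
        if len(pos) < 2:
            continue
        d = np.diff(pos)
        xs.append(lev[:-1])
        ys.append(lev[1:])
        ds.append(d)
    if not ds:
        return pd.DataFrame(columns=["distance", "r", "n_pairs"])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    d = np.concatenate(ds)
    rows = []
    for dist in np.unique(d):
        if dist > max_dist:
            break
        sel = d == dist
        if int(sel.sum()) < min_pairs:
            continue
        rows.append(
            {"distance": int(dist), "r": _pearson(x[sel], y[sel]), "n_pairs": int(sel.sum())}
        )
    return pd.DataFrame(rows)


def detrended_periodogram(curve: pd.DataFrame, detrend_span: int = 5) -> pd.DataFrame:
    """Descriptive periodogram of the residual distance-correlation curve.

    The curve is interpolated to a regular 1-bp grid, detrended with a
    centered moving average, and Fourier-transformed; periods are in bp.
    """
    d = curve["distance"].to_numpy()
    r = curve["r"].to_numpy()
    grid = np.arange(d.min(), d.max() + 1)
    rg = np.interp(grid, d, r)
    kernel = np.ones(2 * detrend_span + 1) / (2 * detrend_span + 1)
    trend = np.convolve(rg, kernel, mode="same")
    resid = rg - trend
    spec = np.abs(np.fft.rfft(resid - resid.mean())) ** 2
    freq = np.fft.rfftfreq(len(resid), d=1.0)
    with np.errstate(divide="ignore"):
        period = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-12), np.inf)
    return pd.DataFrame({"period": period[1:], "power": spec[1:]})


def pmd_cross_sample_correlation(
    cpgs_a: pd.DataFrame,
    cpgs_b: pd.DataFrame,
    pmds_a: RegionSet,
    pmds_b: Optional[RegionSet] = None,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Per-PMD Pearson correlation of single-CpG levels between two samples.

    Only CpGs present (after identical filtering) in both tables enter;
    when two PMD annotations are given, the domains are their overlap
    components.  PMDs with fewer than ``min_shared`` shared CpGs are
    skipped and counted.
    """
    common = pmds_a if pmds_b is None else pmds_a.intersect(pmds_b, label="PMD_common")
    merged = cpgs_a.merge(
        cpgs_b, on=["chrom", "pos"], suffixes=("_a", "_b")
    )
    rows = []
    n_skipped = 0
    for chrom, sub in merged.groupby("chrom", sort=True):
        idx = common.interval_index(chrom, sub["pos"].to_numpy())
        sub = sub.assign(_pmd=idx)
        for pmd_id, grp in sub[sub["_pmd"] >= 0].groupby("_pmd"):
            if len(grp) < min_shared:
                n_skipped += 1
                continue
            rows.append(
                {
                    "pmd_id": int(pmd_id),
                    "chrom": chrom,
                    "n_cpgs": len(grp),
                    "r": _pearson(grp["level_a"].to_numpy(), grp["level_b"].to_numpy()),
                }
            )
    if n_skipped:
        log.info("skipped %d PMDs with < %d shared CpGs", n_skipped, min_shared)
    return pd.DataFrame(rows, columns=["pmd_id", "chrom", "n_cpgs", "r"])


def correlation_histogram(per_pmd: pd.DataFrame, bins: int = 20) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram summary of the per-PMD correlation coefficients."""
    return np.histogram(per_pmd["r"].dropna(), bins=bins, range=(-1, 1))
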