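"""Nucleosome occupancy around CpGs from MNase read starts.

Read 5' ends are shifted half a nucleosome footprint (74 bp) toward the
fragment midpoint — start+74 on the plus strand, start-74 on the minus
strand (whose recorded 5' end is its largest coordinate) — so that shifted
centers mark dyads.  Reads starting exactly at an interrogated CpG are
excluded before shifting (MNase cutting at CpGs produces sharp artifacts
in CpG-anchored averages).  Composite profiles average the center counts
around CpGs stratified into methylation-level bins, expressed as
enrichment over the mean across all CpGs; a positional-count regression
bounds how much methylation the MNase signal can predict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.linalg

log = logging.getLogger(__name__)

SHIFT = 74  # half the 147 bp nucleosome footprint, rounded up


@dataclass
class MNaseTrack:
    """Per-chromosome base-resolution counts of shifted read centers."""

    counts: Dict[str, np.ndarray]
    n_reads: int = 0
    n_excluded_cpg_start: int = 0
    n_off_chromosome: int = 0

    @property
    def n_retained(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def shift_and_count(
    reads: pd.DataFrame,
    cpgs: pd.DataFrame,
    chrom_lengths: Dict[str, int],
) -> MNaseTrack:
    """Accumulate shifted read centers, excluding CpG-start reads.

    ``reads`` carries single-base 5'-end coordinates and strand; reads
    whose unshifted 5' end equals either base of an interrogated CpG are
    dropped, as are reads whose shifted center falls off the chromosome.
    """
    counts = {c: np.zeros(l, dtype=np.int32) for c, l in chrom_lengths.items()}
    n_reads = len(reads)
    n_excluded = 0
    n_off = 0
    cpg_pos = {
        chrom: np.unique(
            np.concatenate([sub["pos"].to_numpy(), sub["pos"].to_numpy() + 1])
        )
        for chrom, sub in cpgs.groupby("chrom")
    }
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in counts:
            n_off += len(sub)
            continue
        starts = sub["start"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        banned = cpg_pos.get(chrom)
        if banned is not None and len(banned):
            hit = np.isin(starts, banned)
            n_excluded += int(hit.sum())
            starts, plus = starts[~hit], plus[~hit]
        centers = np.where(plus, starts + SHIFT, starts - SHIFT)
        inside = (centers >= 0) & (centers < len(counts[chrom]))
        n_off += int((~inside).sum())
        np.add.at(counts[chrom], centers[inside], 1)
    track = MNaseTrack(
        counts=counts,
        n_reads=n_reads,
        n_excluded_cpg_start=n_excluded,
        n_off_chromosome=n_off,
    )
    assert track.n_retained == n_reads - n_excluded - n_off
    return track


def _usable_sites(
    track: MNaseTrack, cpgs: pd.DataFrame, window: int
) -> pd.DataFrame:
    """CpGs whose +-window count vector lies fully on the chromosome."""
    keep = []
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        if chrom not in track.counts:
            continue
        pos = sub["pos"].to_numpy()
        ok = (pos >= window) & (pos + window < len(track.counts[chrom]))
        if ok.any():
            keep.append(sub[ok])
    if not keep:
        return cpgs.iloc[:0]
    return pd.concat(keep, ignore_index=True)


def _gather_windows(
    track: MNaseTrack, sites: pd.DataFrame, window: int
) -> np.ndarray:
    """Count windows (n_sites, 2*window+1), float32, in ``sites`` row order."""
    offs = np.arange(-window, window + 1)
    out = np.empty((len(sites), 2 * window + 1), dtype=np.float32)
    for chrom, sub in sites.groupby("chrom", sort=False):
        arr = track.counts[chrom]
        loc = sites.index.get_indexer(sub.index)
        pos = sub["pos"].to_numpy()
        for start in range(0, len(pos), 4096):
            chunk = slice(start, start + 4096)
            out[loc[chunk]] = arr[pos[chunk][:, None] + offs[None, :]]
    return out


def composite_profiles(
    track: MNaseTrack,
    cpgs: pd.DataFrame,
    window: int = 1000,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Methylation-stratified composite center-count profiles.

    CpGs are split into ``n_bins`` equally spaced level bins (half-open,
    top bin closed).  Each bin's mean count per offset is divided by the
    grand mean over all CpGs and offsets, giving enrichment relative to
    the average CpG; empty bins are absent from the output.
    """
    sites = _usable_sites(track, cpgs, window)
    if len(sites) == 0:
        return pd.DataFrame(columns=["bin", "lo", "hi", "n_cpgs", "offset", "enrichment"])
    edges = np.linspace(0, 1, n_bins + 1)
    levels = sites["level"].to_numpy()
    which = np.clip(np.searchsorted(edges, levels, side="right") - 1, 0, n_bins - 1)
    offs = np.arange(-window, window + 1)
    sums = np.zeros((n_bins, 2 * window + 1))
    n_per_bin = np.bincount(which, minlength=n_bins)
    for b in range(n_bins):
        bin_sites = sites[which == b]
        for chrom, sub in bin_sites.groupby("chrom", sort=False):
            arr = track.counts[chrom]
            pos = sub["pos"].to_numpy()
            for start in range(0, len(pos), 4096):
                w = arr[pos[start : start + 4096][:, None] + offs[None, :]]
                sums[b] += w.sum(axis=0)
    grand_mean = sums.sum() / (len(sites) * (2 * window + 1))
    rows = []
    for b in range(n_bins):
        if n_per_bin[b] == 0:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "bin": b,
                    "lo": edges[b],
                    "hi": edges[b + 1],
                    "n_cpgs": int(n_per_bin[b]),
                    "offset": offs,
                    "enrichment": sums[b] / n_per_bin[b] / grand_mean,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def mnase_regression(
    track: MNaseTrack,
    cpgs: pd.DataFrame,
    window: int = 200,
    n_train: int = 20_000,
    n_test: int = 10_000,
    seed: int = 0,
) -> Tuple[float, int, int]:
    """Held-out correlation of a positional-count linear model.

    Ordinary least squares of methylation level on the shifted-center
    counts at every offset within +-window of the CpG (2*window+1
    predictors plus intercept); returns (pearson r on the held-out set,
    n_train, n_test).
    """
    sites = _usable_sites(track, cpgs, window)
    n = len(sites)
    if n_train + n_test > n:
        raise ValueError(f"n_train + n_test exceeds {n} usable sites")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train : n_train + n_test])
    levels = sites["level"].to_numpy()
    Xtr = _gather_windows(track, sites.iloc[tr].reset_index(drop=True), window)
    Xte = _gather_windows(track, sites.iloc[te].reset_index(drop=True), window)
    Xtr = np.column_stack([Xtr, np.ones(len(tr), dtype=np.float32)])
    beta, *_ = scipy.linalg.lstsq(Xtr.astype(np.float64), levels[tr], cond=1e-10)
    pred = np.column_stack([Xte, np.ones(len(te), dtype=np.float32)]).astype(np.float64) @ beta
    obs = levels[te]
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan"), len(tr), len(te)
    return float(np.corrcoef(pred, obs)[0, 1]), len(tr), len(te)
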