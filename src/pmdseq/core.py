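"""Strand combining, CpG filtering and interval annotation.

The entry table is a per-strand cytosine call table (chrom, pos, strand,
meth, total) as produced by bisulfite callers.  Calls on the two strands of
one CpG are combined into a single record keyed by the position of the C on
the plus strand; methylation level is the combined meth/total fraction.
All coordinates are 0-based; strand '-' calls sit at pos+1 of their CpG.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet
from .sequence import Genome

log = logging.getLogger(__name__)

CPG_COLUMNS = ["chrom", "pos", "meth", "total", "level"]


def combine_strands(
    calls: pd.DataFrame, genome: Optional[Genome] = None
) -> pd.DataFrame:
    """Combine per-strand cytosine calls into per-CpG records.

    Plus-strand calls at ``pos`` and minus-strand calls at ``pos+1`` are
    summed into one CpG at ``pos``; CpGs observed on a single strand keep
    that strand's counts.  When a genome is supplied, calls whose reference
    dinucleotide is not CG are rejected with a warning.  Negative counts
    are a hard error.
    """
    df = calls.copy()
    if (df["meth"] < 0).any() or (df["total"] < 0).any():
        raise ValueError("negative counts in call table")
    if (df["meth"] > df["total"]).any():
        raise ValueError("meth exceeds total in call table")
    cpg_pos = np.where(df["strand"] == "-", df["pos"] - 1, df["pos"]).astype(np.int64)
    df = df.assign(cpg_pos=cpg_pos)
    if genome is not None:
        ok = np.ones(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                ok[sub.index] = False
                continue
            codes = genome[chrom]
            p = sub["cpg_pos"].to_numpy()
            good = (p >= 0) & (p + 1 < len(codes))
            good[good] = (codes[p[good]] == 1) & (codes[p[good] + 1] == 2)
            ok[sub.index] = good
        if (~ok).any():
            log.warning("rejected %d calls not at a reference CpG", int((~ok).sum()))
            df = df[ok]
    grouped = (
        df.groupby(["chrom", "cpg_pos"], sort=True)[["meth", "total"]]
        .sum()
        .reset_index()
        .rename(columns={"cpg_pos": "pos"})
    )
    grouped = grouped[grouped["total"] > 0].reset_index(drop=True)
    grouped["level"] = grouped["meth"] / grouped["total"]
    return grouped[CPG_COLUMNS]


def apply_filters(
    cpgs: pd.DataFrame,
    islands: RegionSet,
    dhs: Optional[RegionSet] = None,
    snps: Optional[pd.DataFrame] = None,
    min_cov: int = 10,
    autosomes: Optional[Sequence[str]] = None,
    island_extend: int = 100,
) -> pd.DataFrame:
    """Apply the standard CpG filters.

    Retains CpGs that (a) lie on the configured autosomes, (b) reach the
    minimum combined coverage, (c) fall outside CpG islands extended by
    ``island_extend`` bp on each side, (d) fall outside DHS when a DHS set
    is given, and (e) overlap no SNP with either base of the dinucleotide.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    df = cpgs
    if autosomes is not None:
        df = df[df["chrom"].isin(list(autosomes))]
    df = df[df["total"] >= min_cov]
    keep = np.ones(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        loc = df.index.get_indexer(sub.index)
        p = sub["pos"].to_numpy()
        drop = islands.overlaps(chrom, p, extend=island_extend)
        drop |= islands.overlaps(chrom, p + 1, extend=island_extend)
        if dhs is not None:
            drop |= dhs.overlaps(chrom, p) | dhs.overlaps(chrom, p + 1)
        if snps is not None and len(snps):
            spos = snps.loc[snps["chrom"] == chrom, "pos"].to_numpy()
            if len(spos):
                drop |= np.isin(p, spos) | np.isin(p + 1, spos)
        keep[loc] = ~drop
    out = df[keep].reset_index(drop=True)
    if out.empty:
        log.warning("all CpGs removed by filtering")
    return out


def annotate_intervals(
    cpgs: pd.DataFrame,
    pmds: RegionSet,
    repeats: Optional[RegionSet] = None,
    min_pmd_length: int = 200_000,
) -> pd.DataFrame:
    """Label CpGs as inside/outside retained PMDs and with a repeat class.

    PMDs shorter than ``min_pmd_length`` are discarded before annotation
    (only long domains form the high-confidence set); a CpG is outside PMDs
    if it overlaps no retained PMD.  The repeat class is the class tag of
    the first overlapping repeat interval, or 'none'.
    """
    retained = pmds.filter_min_length(min_pmd_length)
    n_drop = len(pmds) - len(retained)
    if n_drop:
        log.info("discarded %d PMDs shorter than %d bp", n_drop, min_pmd_length)
    df = cpgs.copy()
    in_pmd = np.zeros(len(df), dtype=bool)
    rep_class = np.full(len(df), "none", dtype=object)
    for chrom, sub in df.groupby("chrom", sort=False):
        loc = df.index.get_indexer(sub.index)
        p = sub["pos"].to_numpy()
        in_pmd[loc] = retained.overlaps(chrom, p)
        if repeats is not None:
            rep_class[loc] = repeats.first_class(chrom, p)
    df["pmd"] = in_pmd
    df["repeat_class"] = rep_class
    return df


def level_distributions(
    cpgs: pd.DataFrame, by: str = "repeat_class", min_cpgs: int = 1000
) -> pd.DataFrame:
    """Per-stratum methylation-level summaries.

    Strata with fewer than ``min_cpgs`` CpGs are suppressed, matching the
    reporting rule used for per-repeat-class distributions.
    """
    rows = []
    for key, sub in cpgs.groupby(by):
        if len(sub) < min_cpgs:
            continue
        lv = sub["level"]
        rows.append(
            {
                by: key,
                "n": len(sub),
                "mean": lv.mean(),
                "median": lv.median(),
                "q25": lv.quantile(0.25),
                "q75": lv.quantile(0.75),
            }
        )
    return pd.DataFrame(rows)
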