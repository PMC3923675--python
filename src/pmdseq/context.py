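"""Correlation of methylation between CpGs with identical flanking sequence.

CpGs are grouped by the exact L-bp sequence window centered on the CpG
(L/2 - 1 bases, then CG, then L/2 - 1 bases).  A group of two yields its
pair; larger groups contribute exactly one uniformly chosen pair, so every
CpG enters at most one pair per context length.  The Pearson correlation of
the paired levels, as a function of L, measures how much of the methylation
level is determined by local sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .sequence import Genome, N_CODE

log = logging.getLogger(__name__)


def max_unique_overhang(read_length: int, context_length: int) -> int:
    """Read bases available outside a centered context for unique mapping.

    A read must overlap the central CpG by at least one base; the part
    protruding past the context window (which is identical between the
    paired loci, hence uninformative for mapping) is largest when the read
    barely touches the CpG, leaving read_length - 1 bases beyond it, of
    which (context_length - 2) / 2 are still inside the window.
    """
    return read_length - 1 - (context_length - 2) // 2


@dataclass
class ContextPair:
    """Two distinct CpGs sharing an identical L-bp centered window."""

    length: int
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    level_a: float
    level_b: float
    class_a: str = "none"
    class_b: str = "none"


def _windows(cpgs: pd.DataFrame, genome: Genome, length: int):
    """Per-site window bytes; None where the window is invalid."""
    half = length // 2 - 1
    keys = np.full(len(cpgs), None, dtype=object)
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        codes = genome[chrom]
        loc = cpgs.index.get_indexer(sub.index)
        for j, p in zip(loc, sub["pos"].to_numpy()):
            lo, hi = p - half, p + 2 + half
            if lo < 0 or hi > len(codes):
                continue
            w = codes[lo:hi]
            if (w == N_CODE).any():
                continue
            keys[j] = w.tobytes()
    return keys


def context_pairs(
    cpgs: pd.DataFrame,
    genome: Genome,
    length: int,
    seed: int = 0,
) -> list[ContextPair]:
    """All identical-context pairs at one context length.

    Groups of size one are dropped; groups larger than two contribute one
    seeded uniformly random pair.  Windows containing N, or truncated at a
    chromosome edge, exclude their CpG.
    """
    if length % 2 != 0:
        raise ValueError("context length must be even")
    rng = np.random.default_rng(seed)
    df = cpgs.reset_index(drop=True)
    keys = _windows(df, genome, length)
    groups: Dict[bytes, list[int]] = {}
    for i, k in enumerate(keys):
        if k is not None:
            groups.setdefault(k, []).append(i)
    has_class = "repeat_class" in df.columns
    pairs: list[ContextPair] = []
    chroms = df["chrom"].to_numpy()
    positions = df["pos"].to_numpy()
    levels = df["level"].to_numpy()
    classes = df["repeat_class"].to_numpy() if has_class else None
    for key in sorted(groups):  # deterministic iteration order
        members = groups[key]
        if len(members) < 2:
            continue
        if len(members) == 2:
            a, b = members
        else:
            a, b = rng.choice(members, size=2, replace=False)
        pairs.append(
            ContextPair(
                length=length,
                chrom_a=chroms[a],
                pos_a=int(positions[a]),
                chrom_b=chroms[b],
                pos_b=int(positions[b]),
                level_a=float(levels[a]),
                level_b=float(levels[b]),
                class_a=str(classes[a]) if has_class else "none",
                class_b=str(classes[b]) if has_class else "none",
            )
        )
    return pairs


def pair_correlation(pairs: Iterable[ContextPair], seed: int = 0):
    """Pearson r of paired levels with seeded pair-order randomization."""
    pairs = list(pairs)
    n = len(pairs)
    if n < 3:
        return float("nan"), n
    rng = np.random.default_rng(seed)
    a = np.array([p.level_a for p in pairs])
    b = np.array([p.level_b for p in pairs])
    flip = rng.random(n) < 0.5
    x = np.where(flip, b, a)
    y = np.where(flip, a, b)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), n
    return float(np.corrcoef(x, y)[0, 1]), n


def correlation_curve(
    cpgs: pd.DataFrame,
    genome: Genome,
    lengths: Iterable[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Identical-context correlation as a function of context length."""
    rows = []
    for L in lengths:
        pairs = context_pairs(cpgs, genome, L, seed=seed)
        r, n = pair_correlation(pairs, seed=seed)
        rows.append({"length": L, "r": r, "n_pairs": n})
    return pd.DataFrame(rows)


def stratify_by_repeat(
    pairs: Iterable[ContextPair], min_pairs: int = 100, seed: int = 0
) -> Dict[str, Tuple[float, int]]:
    """Per-repeat-class pair correlation.

    A pair belongs to a repeat class only if both CpGs share it, otherwise
    to 'mixed'; CpGs outside repeats form the 'non-repeat' class.  Classes
    with fewer than ``min_pairs`` pairs are suppressed.
    """
    by_class: Dict[str, list[ContextPair]] = {}
    for p in pairs:
        ca = "non-repeat" if p.class_a == "none" else p.class_a
        cb = "non-repeat" if p.class_b == "none" else p.class_b
        cls = ca if ca == cb else "mixed"
        by_class.setdefault(cls, []).append(p)
    out: Dict[str, Tuple[float, int]] = {}
    for cls, members in sorted(by_class.items()):
        if len(members) < min_pairs:
            continue
        r, n = pair_correlation(members, seed=seed)
        out[cls] = (r, n)
    return out
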