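"""Labeled genomic interval sets with overlap queries.

Intervals are 0-based half-open.  A :class:`RegionSet` holds one label
(PMD, CpG_island, DHS, repeat ...) and optionally a class tag per interval
(repeat class such as LINE/SINE/LTR/SVA).  Membership queries run on merged
per-chromosome arrays via searchsorted; class-tag queries, where nested and
overlapping intervals are legitimate, go through an interval tree and
resolve ties in favour of the first overlapping interval in sorted order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide variant; ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    heterozygous: bool = True

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")


class RegionSet:
    """A labeled set of genomic intervals."""

    def __init__(
        self,
        label: str,
        intervals: Iterable[Tuple[str, int, int]] | pd.DataFrame,
        class_tags: Optional[Sequence[str]] = None,
    ):
        if isinstance(intervals, pd.DataFrame):
            df = intervals.iloc[:, :3].copy()
            df.columns = ["chrom", "start", "end"]
        else:
            df = pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])
        if class_tags is not None:
            df["class_tag"] = list(class_tags)
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"{label}: empty or inverted interval")
        self.label = label
        self._df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        # merged (membership) representation
        self._merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self._df.groupby("chrom", sort=True):
            starts, ends = _merge(sub["start"].to_numpy(), sub["end"].to_numpy())
            self._merged[chrom] = (starts, ends)
        self._trees: Optional[Dict[str, IntervalTree]] = None

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for row in self._df.itertuples(index=False):
            yield (row.chrom, int(row.start), int(row.end))

    @property
    def has_classes(self) -> bool:
        return "class_tag" in self._df.columns

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def total_length(self) -> int:
        return int(
            sum((e - s).sum() for s, e in (v for v in self._merged.values()))
        )

    # -- queries ----------------------------------------------------------
    def overlaps(self, chrom: str, pos, extend: int = 0) -> np.ndarray:
        """Boolean mask: does each position fall in an interval (+- extend)?"""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._merged:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = self._merged[chrom]
        # merged intervals have strictly increasing starts and ends, so the
        # candidate with the largest start-extend <= pos has the largest end
        idx = np.searchsorted(starts - extend, pos, side="right") - 1
        hit = idx >= 0
        hit[hit] = pos[hit] < ends[idx[hit]] + extend
        return hit

    def first_class(self, chrom: str, pos) -> np.ndarray:
        """Class tag of the first overlapping interval, or 'none'."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        out = np.full(len(pos), "none", dtype=object)
        if chrom not in set(self._df["chrom"]):
            return out
        if self._trees is None:
            self._build_trees()
        tree = self._trees.get(chrom)
        if tree is None:
            return out
        for i, p in enumerate(pos):
            hits = tree[int(p)]
            if hits:
                best = min(hits, key=lambda iv: (iv.begin, iv.end))
                if len(hits) > 1:
                    log.debug("position %s:%d in %d overlapping intervals; "
                              "first in sorted order wins", chrom, p, len(hits))
                out[i] = best.data
        return out

    def _build_trees(self) -> None:
        self._trees = {}
        tags = (
            self._df["class_tag"]
            if self.has_classes
            else pd.Series([self.label] * len(self._df))
        )
        for chrom, sub in self._df.assign(tag=tags.values).groupby("chrom"):
            tree = IntervalTree()
            for s, e, t in zip(sub["start"], sub["end"], sub["tag"]):
                tree[int(s) : int(e)] = t
            self._trees[chrom] = tree

    # -- derived sets ------------------------------------------------------
    def filter_min_length(self, min_length: int) -> "RegionSet":
        df = self._df[(self._df["end"] - self._df["start"]) >= min_length]
        tags = df["class_tag"].tolist() if self.has_classes else None
        return RegionSet(self.label, df.iloc[:, :3], tags)

    def intersect(self, other: "RegionSet", label: Optional[str] = None) -> "RegionSet":
        """Connected components of the pairwise intersection of two sets."""
        rows = []
        for chrom in sorted(set(self._merged) & set(other._merged)):
            s1, e1 = self._merged[chrom]
            s2, e2 = other._merged[chrom]
            i = j = 0
            while i < len(s1) and j < len(s2):
                lo = max(s1[i], s2[j])
                hi = min(e1[i], e2[j])
                if lo < hi:
                    rows.append((chrom, int(lo), int(hi)))
                if e1[i] <= e2[j]:
                    i += 1
                else:
                    j += 1
        return RegionSet(label or self.label, rows)

    def interval_index(self, chrom: str, pos) -> np.ndarray:
        """Index of the containing merged interval per position, -1 outside.

        Indices are global over the chromosome-sorted merged intervals, so
        they can serve as stable per-domain identifiers.
        """
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        out = np.full(len(pos), -1, dtype=np.int64)
        offset = 0
        for c in sorted(self._merged):
            starts, ends = self._merged[c]
            if c == chrom:
                idx = np.searchsorted(starts, pos, side="right") - 1
                ok = idx >= 0
                ok[ok] = pos[ok] < ends[idx[ok]]
                out[ok] = idx[ok] + offset
                return out
            offset += len(starts)
        return out


def _merge(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s: List[int] = []
    out_e: List[int] = []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)
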