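"""Low-level genomic interval arithmetic on numpy arrays.

Coordinates are 0-based half-open ``[start, end)`` everywhere inside the
package. BED files use the same convention, so readers and writers never
shift coordinates; any 1-based input format is converted at its reader.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "merge_intervals",
    "overlap_any",
    "overlap_candidates",
    "ChromIntervals",
]


def merge_intervals(
    starts, ends, merge_touching: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals on one chromosome.

    Overlap means >=1 shared base; book-ended intervals ([0,10) and
    [10,20)) are kept separate unless ``merge_touching`` is set (wanted
    for coverage masks, not for anchor nodes).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    if np.any(ends < starts):
        raise ValueError("interval with end < start")
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cm = np.maximum.accumulate(e)
    if merge_touching:
        breaks = s[1:] > cm[:-1]
    else:
        breaks = s[1:] >= cm[:-1]
    group_first = np.concatenate([[0], np.flatnonzero(breaks) + 1])
    group_id = np.concatenate([[0], np.cumsum(breaks)])
    out_s = s[group_first]
    out_e = np.zeros(len(group_first), dtype=np.int64)
    np.maximum.at(out_e, group_id, e)
    return out_s, out_e


def overlap_any(starts, ends, qs, qe) -> np.ndarray:
    """Boolean per query: does [qs, qe) overlap any interval by >=1 bp?

    ``starts``/``ends`` need not be disjoint; they are merged internally.
    """
    ms, me = merge_intervals(starts, ends)
    qs = np.atleast_1d(np.asarray(qs, dtype=np.int64))
    qe = np.atleast_1d(np.asarray(qe, dtype=np.int64))
    if ms.size == 0:
        return np.zeros(qs.shape, dtype=bool)
    idx = np.searchsorted(ms, qe, side="left")  # last interval starting before qe
    hit = idx > 0
    safe = np.maximum(idx - 1, 0)
    hit &= me[safe] > qs
    return hit


def overlap_candidates(
    starts: np.ndarray, ends: np.ndarray, qs: int, qe: int
) -> np.ndarray:
    """Indices (into the start-sorted arrays) of intervals overlapping [qs, qe).

    ``starts`` must be sorted ascending; intervals may overlap each other.
    Uses the running maximum of ends to bound the scan window.
    """
    if starts.size == 0:
        return np.empty(0, dtype=np.int64)
    cm = np.maximum.accumulate(ends)
    lo = np.searchsorted(cm, qs, side="right")
    hi = np.searchsorted(starts, qe, side="left")
    if lo >= hi:
        return np.empty(0, dtype=np.int64)
    cand = np.arange(lo, hi)
    return cand[ends[cand] > qs]


@dataclass
class ChromIntervals:
    """Merged, start-sorted interval sets keyed by chromosome.

    The canonical container for peak sets, mark regions, masks, and the
    free (unmasked) genome. Construction merges overlaps, so membership
    queries are O(log n) searchsorted lookups.
    """

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, merge_touching: bool = False
    ) -> "ChromIntervals":
        by_chrom = {}
        if len(df):
            for chrom, sub in df.groupby("chrom", sort=True):
                by_chrom[str(chrom)] = merge_intervals(
                    sub["start"].to_numpy(), sub["end"].to_numpy(), merge_touching
                )
        return cls(by_chrom)

    @classmethod
    def empty(cls) -> "ChromIntervals":
        return cls({})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.by_chrom):
            s, e = self.by_chrom[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)

    def overlaps(self, chrom: str, qs, qe) -> np.ndarray:
        qs = np.atleast_1d(np.asarray(qs, dtype=np.int64))
        qe = np.atleast_1d(np.asarray(qe, dtype=np.int64))
        if chrom not in self.by_chrom:
            return np.zeros(qs.shape, dtype=bool)
        s, e = self.by_chrom[chrom]
        idx = np.searchsorted(s, qe, side="left")
        hit = idx > 0
        safe = np.maximum(idx - 1, 0)
        hit &= e[safe] > qs
        return hit

    def overlaps_frame(self, df: pd.DataFrame, start="start", end="end") -> np.ndarray:
        # positional, so semantics do not depend on the frame's index
        out = np.zeros(len(df), dtype=bool)
        chroms = df["chrom"].to_numpy()
        ss = df[start].to_numpy()
        ee = df[end].to_numpy()
        for chrom in np.unique(chroms):
            m = chroms == chrom
            out[m] = self.overlaps(str(chrom), ss[m], ee[m])
        return out

    def total_length(self) -> int:
        return int(
            sum(int((e - s).sum()) for s, e in self.by_chrom.values())
        )

    def complement(self, chrom_lengths: dict[str, int]) -> "ChromIntervals":
        out = {}
        for chrom, length in chrom_lengths.items():
            if chrom in self.by_chrom:
                s, e = self.by_chrom[chrom]
                s = np.clip(s, 0, length)
                e = np.clip(e, 0, length)
                cs = np.concatenate([[0], e])
                ce = np.concatenate([s, [length]])
                keep = ce > cs
                out[chrom] = (cs[keep], ce[keep])
            else:
                out[chrom] = (
                    np.array([0], dtype=np.int64),
                    np.array([length], dtype=np.int64),
                )
        return ChromIntervals(out)

    def union(self, other: "ChromIntervals", merge_touching: bool = True) -> "ChromIntervals":
        out = {}
        for chrom in sorted(set(self.by_chrom) | set(other.by_chrom)):
            parts_s, parts_e = [], []
            for src in (self, other):
                if chrom in src.by_chrom:
                    s, e = src.by_chrom[chrom]
                    parts_s.append(s)
                    parts_e.append(e)
            out[chrom] = merge_intervals(
                np.concatenate(parts_s), np.concatenate(parts_e), merge_touching
            )
        return ChromIntervals(out)
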