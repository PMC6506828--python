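"""Histone-mark regions, enhancer states, bin statistics, and
random-sampling enrichment.

Mark peaks (H3K27ac, H3K4me1) are standardized to a minimum length of
2 kb and merged; regions within 1 kb of a TSS are promoters, the rest
putative distal enhancers. Distal regions carrying both marks are
"active" enhancers, H3K4me1 alone "poised". 200-bp bins are binarized
against a genome-wide Poisson background and tested for WT/MUT
differential enrichment with a 2x2 chi-square. Observed peak-set
overlaps are calibrated against random interval sets sampled from the
mappable, unmasked genome.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ChromIntervals, merge_intervals

__all__ = [
    "standardize_peaks",
    "split_promoter_distal",
    "enhancer_state",
    "binarize_bins",
    "differential_bins",
    "build_unmappable_mask",
    "empirical_enrichment",
    "EnrichmentResult",
]


def standardize_peaks(peaks: pd.DataFrame, min_len: int = 2_000) -> pd.DataFrame:
    """Extend every peak shorter than ``min_len`` symmetrically around its
    midpoint, then merge overlapping results. Idempotent."""
    if len(peaks) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    s = peaks["start"].to_numpy(dtype=np.int64)
    e = peaks["end"].to_numpy(dtype=np.int64)
    short = (e - s) < min_len
    mid = (s + e) // 2
    s = np.where(short, mid - min_len // 2, s)
    e = np.where(short, mid - min_len // 2 + min_len, e)
    s = np.maximum(s, 0)
    rows = []
    df = pd.DataFrame({"chrom": peaks["chrom"].to_numpy(), "start": s, "end": e})
    for chrom, sub in df.groupby("chrom", sort=True):
        ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        rows.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    return pd.concat(rows, ignore_index=True)


def split_promoter_distal(
    regions: pd.DataFrame, tss_by_chrom: dict[str, np.ndarray], window: int = 1_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition regions into promoter (within ``window`` bp of a TSS,
    endpoint inclusive) and distal sets."""
    if len(regions) == 0:
        empty = regions.copy()
        return empty, empty.copy()
    win_frames = []
    for chrom, tss in tss_by_chrom.items():
        tss = np.asarray(tss, dtype=np.int64)
        win_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": tss - window, "end": tss + window + 1}
            )
        )
    prox = ChromIntervals.from_frame(pd.concat(win_frames, ignore_index=True))
    is_prom = prox.overlaps_frame(regions)
    return (
        regions[is_prom].reset_index(drop=True),
        regions[~is_prom].reset_index(drop=True),
    )


def enhancer_state(
    query: pd.DataFrame, k27: pd.DataFrame, k4: pd.DataFrame
) -> pd.Series:
    """active (both marks), poised (H3K4me1 only), k27_only, or none."""
    k27_idx = ChromIntervals.from_frame(k27)
    k4_idx = ChromIntervals.from_frame(k4)
    h27 = k27_idx.overlaps_frame(query)
    h4 = k4_idx.overlaps_frame(query)
    state = np.where(
        h27 & h4, "active", np.where(h4, "poised", np.where(h27, "k27_only", "none"))
    )
    return pd.Series(state, index=query.index, name="enhancer_state")


def binarize_bins(
    counts: np.ndarray,
    p_threshold: float = 1e-4,
    lam: float | None = None,
    unmasked: np.ndarray | None = None,
) -> np.ndarray:
    """Bin enriched iff the upper-tail Poisson probability P(X >= r) under
    the genome-wide mean rate falls below ``p_threshold``.

    ``lam`` defaults to the mean count over unmasked bins (all bins if no
    mask is given).
    """
    counts = np.asarray(counts)
    if lam is None:
        pool = counts if unmasked is None else counts[unmasked]
        if pool.size == 0 or pool.sum() == 0:
            raise ValueError("cannot estimate background rate from empty/zero bins")
        lam = float(pool.mean())
    tail = stats.poisson.sf(counts - 1, lam)  # P(X >= r)
    return tail < p_threshold


def differential_bins(
    r_wt, r_mut, R_wt: int, R_mut: int,
    p_threshold: float = 1e-4,
    yates: bool = False,
):
    """Chi-square test of WT vs MUT read counts for a region.

    The 2x2 table is [[r_wt, R_wt - r_wt], [r_mut, R_mut - r_mut]] with
    R_* the genome-wide mapped totals; 1 df, no continuity correction by
    default. Returns (p, is_differential); vectorised over r_wt/r_mut.
    """
    r_wt = np.asarray(r_wt, dtype=np.float64)
    r_mut = np.asarray(r_mut, dtype=np.float64)
    if R_wt <= 0 or R_mut <= 0:
        raise ValueError("totals must be > 0")
    if np.any(r_wt < 0) or np.any(r_mut < 0) or np.any(r_wt > R_wt) or np.any(r_mut > R_mut):
        raise ValueError("counts must satisfy 0 <= r <= R")
    a, b = r_wt, R_wt - r_wt
    c, d = r_mut, R_mut - r_mut
    n = a + b + c + d
    exp_min = np.minimum.reduce(
        [(a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)]
    ) / n
    if np.any(exp_min < 1):
        warnings.warn("chi-square expected cell < 1; p-value unreliable", stacklevel=2)
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    chi2 = np.where(np.isfinite(chi2), chi2, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    if p.ndim == 0:
        return float(p), bool(p < p_threshold)
    return p, p < p_threshold


def build_unmappable_mask(
    window_counts: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    window: int = 3_000,
    step: int = 500,
    extra_masks: ChromIntervals | None = None,
) -> ChromIntervals:
    """Unmappable mask from sliding-window coverage.

    ``window_counts[chrom][i]`` is the read count of the window starting
    at ``i * step``. Zero-read windows are masked; the union is merged
    with any gap/blacklist intervals supplied in ``extra_masks``.
    """
    frames = []
    for chrom, counts in window_counts.items():
        counts = np.asarray(counts)
        zero = np.flatnonzero(counts == 0)
        if len(zero) == 0:
            continue
        s = zero.astype(np.int64) * step
        e = np.minimum(s + window, chrom_lengths[chrom])
        frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if frames:
        mask = ChromIntervals.from_frame(
            pd.concat(frames, ignore_index=True), merge_touching=True
        )
    else:
        mask = ChromIntervals.empty()
    if extra_masks is not None:
        mask = mask.union(extra_masks)
    return mask


@dataclass
class EnrichmentResult:
    observed: int
    null_overlaps: np.ndarray
    empirical_p: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_overlaps))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_overlaps, ddof=1))


def _free_runs(mask: ChromIntervals, chrom_lengths: dict[str, int]):
    free = mask.complement(chrom_lengths)
    chroms, starts, lens = [], [], []
    for chrom in sorted(chrom_lengths):
        if chrom in free.by_chrom:
            s, e = free.by_chrom[chrom]
            chroms.extend([chrom] * len(s))
            starts.extend(s.tolist())
            lens.extend((e - s).tolist())
    return np.array(chroms, dtype=object), np.array(starts, dtype=np.int64), np.array(lens, dtype=np.int64)


def sample_random_intervals(
    lengths: np.ndarray,
    mask: ChromIntervals,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    n_sets: int = 1,
) -> list[pd.DataFrame]:
    """``n_sets`` random interval sets, each matching ``lengths`` element
    for element, placed uniformly over mask-free positions (so no sampled
    interval ever intersects the mask)."""
    run_chrom, run_start, run_len = _free_runs(mask, chrom_lengths)
    if len(run_len) == 0:
        raise ValueError("mask leaves no free genome")
    sets = [dict(chrom=[], start=[], end=[]) for _ in range(n_sets)]
    for ell in np.asarray(lengths, dtype=np.int64):
        w = np.maximum(run_len - ell + 1, 0).astype(np.float64)
        if w.sum() == 0:
            raise ValueError(f"no free run can hold an element of length {ell}")
        p = w / w.sum()
        runs = rng.choice(len(w), size=n_sets, p=p)
        offs = (rng.random(n_sets) * w[runs]).astype(np.int64)
        for k in range(n_sets):
            s = int(run_start[runs[k]] + offs[k])
            sets[k]["chrom"].append(run_chrom[runs[k]])
            sets[k]["start"].append(s)
            sets[k]["end"].append(s + int(ell))
    return [pd.DataFrame(d) for d in sets]


def empirical_enrichment(
    query: pd.DataFrame,
    target: pd.DataFrame,
    mask: ChromIntervals,
    chrom_lengths: dict[str, int],
    n_sets: int = 1_000,
    seed: int = 0,
    statistic: str = "elements",
) -> EnrichmentResult:
    """Overlap of ``query`` with ``target`` against matched random sets.

    Each null set has the same number of elements with the same lengths
    as the query, sampled uniformly from the unmasked genome. The overlap
    statistic is the number of elements overlapping the target by >=1 bp
    (or total overlapping bases with ``statistic="bases"``). The add-one
    empirical p, (1 + #{null >= observed}) / (n_sets + 1), is never zero;
    observed above every null reports p = 1/(n_sets+1).
    """
    rng = np.random.default_rng(seed)
    tgt = ChromIntervals.from_frame(target)

    # cumulative covered-bases lookup per chromosome, for the bases statistic
    cum = {}
    for chrom, (s, e) in tgt.by_chrom.items():
        cum[chrom] = (s, e, np.concatenate([[0], np.cumsum(e - s)]))

    def _cov_at(chrom, x):
        s, e, c = cum[chrom]
        idx = np.searchsorted(s, x, side="right") - 1
        safe = np.maximum(idx, 0)
        inside = np.clip(x - s[safe], 0, e[safe] - s[safe])
        return np.where(idx >= 0, c[safe] + inside, 0)

    def stat(df: pd.DataFrame) -> int:
        if statistic == "elements":
            return int(tgt.overlaps_frame(df).sum())
        if statistic == "bases":
            total = 0
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in cum:
                    continue
                total += int(
                    (
                        _cov_at(chrom, sub["end"].to_numpy())
                        - _cov_at(chrom, sub["start"].to_numpy())
                    ).sum()
                )
            return total
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(query)
    lengths = (query["end"] - query["start"]).to_numpy()
    null_sets = sample_random_intervals(lengths, mask, chrom_lengths, rng, n_sets)
    null = np.array([stat(df) for df in null_sets])
    p = (1 + int((null >= observed).sum())) / (n_sets + 1)
    return EnrichmentResult(observed=observed, null_overlaps=null, empirical_p=p)
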