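"""Anchor annotation, nodes, interaction typing, and connectivity.

Anchors are annotated against the gene model with promoter priority:
P if the anchor overlaps any TSS +-promoter_window (default 2.5 kb,
endpoint inclusive), else G on >=1 bp gene-body overlap, else I
(intergenic). Interaction types follow from the two anchor classes:
P-P, P-nonP (promoter-enhancer when the distal anchor carries enhancer
marks), or nonP-nonP. Overlapping anchors merge into nodes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Genome
from .intervals import ChromIntervals, merge_intervals, overlap_candidates

__all__ = [
    "build_nodes",
    "annotate_anchor",
    "annotate_anchors",
    "classify_interaction",
    "annotate_interactions",
    "flag_polII_bound",
    "flag_sox2",
    "interaction_overlap",
    "summarize_connectivity",
]


def build_nodes(
    anchors: pd.DataFrame, genome: Genome | None = None, promoter_window: int = 2_500
) -> pd.DataFrame:
    """Merge overlapping (>=1 bp) anchors into nodes, transitively.

    A node is flagged promoter when the merged interval lies within
    ``promoter_window`` of any TSS (i.e. overlaps the inclusive window).
    """
    rows = []
    for chrom, sub in anchors.groupby("chrom", sort=True):
        s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        # member count per node: anchors whose start falls inside the node
        starts_sorted = np.sort(sub["start"].to_numpy())
        lo = np.searchsorted(starts_sorted, s, side="left")
        hi = np.searchsorted(starts_sorted, e, side="left")
        for ns, ne, k in zip(s, e, hi - lo):
            rows.append({"chrom": chrom, "start": int(ns), "end": int(ne),
                         "n_members": int(k)})
    nodes = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members"])
    if genome is not None and len(nodes):
        prom = ChromIntervals.from_frame(genome.promoter_windows(promoter_window))
        nodes["is_promoter"] = prom.overlaps_frame(nodes)
    elif genome is not None:
        nodes["is_promoter"] = np.array([], dtype=bool)
    return nodes


def annotate_anchors(
    anchors: pd.DataFrame, genome: Genome, promoter_window: int = 2_500
) -> pd.DataFrame:
    """Category (P/G/I) and nearest overlapping gene per anchor.

    Priority P > G > I; a 1-bp overlap suffices at each tier. For P the
    reported gene is the one with the closest TSS among overlapping
    promoter windows; for G, the overlapping gene body with the closest
    midpoint.
    """
    for chrom in anchors["chrom"].unique():
        if chrom not in genome.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r} in anchors")
    prom = genome.promoter_windows(promoter_window)
    genes = genome.genes
    prom_by_chrom = {
        c: sub.sort_values("start").reset_index(drop=True)
        for c, sub in prom.groupby("chrom", sort=False)
    }
    genes_by_chrom = {
        c: sub.sort_values("start").reset_index(drop=True)
        for c, sub in genes.groupby("chrom", sort=False)
    }
    cats = np.empty(len(anchors), dtype=object)
    nearest = np.empty(len(anchors), dtype=object)
    chroms = anchors["chrom"].to_numpy()
    ss = anchors["start"].to_numpy()
    ee = anchors["end"].to_numpy()
    for i in range(len(anchors)):
        chrom, qs, qe = chroms[i], int(ss[i]), int(ee[i])
        mid = (qs + qe) // 2
        cat, gene = "I", None
        pw = prom_by_chrom.get(chrom)
        if pw is not None:
            cand = overlap_candidates(
                pw["start"].to_numpy(), pw["end"].to_numpy(), qs, qe
            )
            if len(cand):
                tss = pw["tss"].to_numpy()[cand]
                best = cand[np.argmin(np.abs(tss - mid))]
                cat, gene = "P", pw.at[int(best), "gene_id"]
        if cat == "I":
            gb = genes_by_chrom.get(chrom)
            if gb is not None:
                cand = overlap_candidates(
                    gb["start"].to_numpy(), gb["end"].to_numpy(), qs, qe
                )
                if len(cand):
                    mids = (
                        gb["start"].to_numpy()[cand] + gb["end"].to_numpy()[cand]
                    ) // 2
                    best = cand[np.argmin(np.abs(mids - mid))]
                    cat, gene = "G", gb.at[int(best), "gene_id"]
        cats[i] = cat
        nearest[i] = gene
    return pd.DataFrame(
        {"category": cats, "nearest_gene": nearest}, index=anchors.index
    )


def annotate_anchor(
    anchor: tuple[str, int, int], genome: Genome, promoter_window: int = 2_500
) -> tuple[str, str | None]:
    """Single-anchor convenience wrapper; returns (category, nearest_gene)."""
    chrom, start, end = anchor
    df = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
    row = annotate_anchors(df, genome, promoter_window).iloc[0]
    return row["category"], row["nearest_gene"]


def classify_interaction(cat_a: str, cat_b: str) -> str:
    """Symmetric interaction type from the two anchor categories."""
    for c in (cat_a, cat_b):
        if c not in ("P", "G", "I"):
            raise ValueError(f"unknown anchor category {c!r}")
    n_p = (cat_a == "P") + (cat_b == "P")
    return {2: "P-P", 1: "P-nonP", 0: "nonP-nonP"}[n_p]


def flag_polII_bound(clusters: pd.DataFrame, polII_peaks: pd.DataFrame) -> np.ndarray:
    """True iff BOTH anchors overlap a Pol II peak by >=1 bp."""
    peaks = ChromIntervals.from_frame(polII_peaks)
    hit_a = peaks.overlaps_frame(
        clusters.rename(columns={"a_start": "start", "a_end": "end"})
    )
    hit_b = peaks.overlaps_frame(
        clusters.rename(columns={"b_start": "start", "b_end": "end"})
    )
    return hit_a & hit_b


def flag_sox2(annotated: pd.DataFrame, sox2_peaks: pd.DataFrame) -> pd.DataFrame:
    """Per interaction: SOX2 on >=1 anchor, and SOX2 on the distal
    (non-promoter) anchor of a P-nonP interaction."""
    peaks = ChromIntervals.from_frame(sox2_peaks)
    hit_a = peaks.overlaps_frame(
        annotated.rename(columns={"a_start": "start", "a_end": "end"})
    )
    hit_b = peaks.overlaps_frame(
        annotated.rename(columns={"b_start": "start", "b_end": "end"})
    )
    is_pnp = (annotated["itype"] == "P-nonP").to_numpy()
    a_is_p = (annotated["cat_a"] == "P").to_numpy()
    distal_hit = np.where(a_is_p, hit_b, hit_a)
    return pd.DataFrame(
        {
            "sox2_a": hit_a,
            "sox2_b": hit_b,
            "sox2_any_anchor": hit_a | hit_b,
            "sox2_distal_anchor": is_pnp & distal_hit,
        },
        index=annotated.index,
    )


def annotate_interactions(
    clusters: pd.DataFrame,
    genome: Genome,
    sox2_peaks: pd.DataFrame | None = None,
    polII_peaks: pd.DataFrame | None = None,
    promoter_window: int = 2_500,
) -> pd.DataFrame:
    """Type every interaction and attach SOX2 / Pol II support flags."""
    out = clusters.copy()
    ann_a = annotate_anchors(
        out.rename(columns={"a_start": "start", "a_end": "end"}), genome, promoter_window
    )
    ann_b = annotate_anchors(
        out.rename(columns={"b_start": "start", "b_end": "end"}), genome, promoter_window
    )
    out["cat_a"] = ann_a["category"]
    out["cat_b"] = ann_b["category"]
    out["gene_a"] = ann_a["nearest_gene"]
    out["gene_b"] = ann_b["nearest_gene"]
    out["itype"] = [
        classify_interaction(a, b) for a, b in zip(out["cat_a"], out["cat_b"])
    ]
    if sox2_peaks is not None:
        out = pd.concat([out, flag_sox2(out, sox2_peaks)], axis=1)
    if polII_peaks is not None:
        out["polII_both"] = flag_polII_bound(out, polII_peaks)
    return out


def interaction_overlap(
    set_a: pd.DataFrame, set_b: pd.DataFrame, window: int
) -> float:
    """Fraction of set_a interactions matched in set_b.

    A match requires both anchor midpoints of some set_b interaction to
    lie within +-window of the corresponding (order-matched) set_a anchor
    midpoints, on the same chromosome.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if len(set_a) == 0:
        return float("nan")

    def mids(df):
        ma = (df["a_start"].to_numpy() + df["a_end"].to_numpy()) // 2
        mb = (df["b_start"].to_numpy() + df["b_end"].to_numpy()) // 2
        lo = np.minimum(ma, mb)
        hi = np.maximum(ma, mb)
        return df["chrom"].to_numpy(), lo, hi

    ca, la, ha = mids(set_a)
    cb, lb, hb = mids(set_b)
    matched = 0
    for chrom in np.unique(ca):
        qa = np.flatnonzero(ca == chrom)
        qb = np.flatnonzero(cb == chrom)
        if len(qb) == 0:
            continue
        d1 = np.abs(la[qa][:, None] - lb[qb][None, :]) <= window
        d2 = np.abs(ha[qa][:, None] - hb[qb][None, :]) <= window
        matched += int((d1 & d2).any(axis=1).sum())
    return matched / len(set_a)


def summarize_connectivity(
    interactions: pd.DataFrame,
    genome: Genome,
    sox2_peaks: pd.DataFrame | None = None,
    promoter_window: int = 2_500,
) -> pd.DataFrame:
    """Per-gene connectivity table.

    A gene is connected when its promoter window overlaps an interaction
    anchor. Partner anchors are counted as promoter partners (P) or
    enhancer partners (non-P); ``has_sox2_pe`` marks genes with at least
    one SOX2-bound non-promoter partner anchor. ``sox2_promoter`` marks
    genes whose own promoter window overlaps a SOX2 peak.
    """
    prom = genome.promoter_windows(promoter_window)
    prom_by_chrom = {
        c: sub.sort_values("start").reset_index(drop=True)
        for c, sub in prom.groupby("chrom", sort=False)
    }
    sox2 = ChromIntervals.from_frame(sox2_peaks) if sox2_peaks is not None else None

    n_enh = {g: 0 for g in genome.genes["gene_id"]}
    n_prom = {g: 0 for g in genome.genes["gene_id"]}
    sox2_pe = {g: False for g in genome.genes["gene_id"]}

    for _, row in interactions.iterrows():
        chrom = row["chrom"]
        pw = prom_by_chrom.get(chrom)
        if pw is None:
            continue
        sides = [
            (int(row["a_start"]), int(row["a_end"]), row["cat_a"],
             int(row["b_start"]), int(row["b_end"]), row["cat_b"]),
            (int(row["b_start"]), int(row["b_end"]), row["cat_b"],
             int(row["a_start"]), int(row["a_end"]), row["cat_a"]),
        ]
        for qs, qe, cat, ps, pe_, pcat in sides:
            cand = overlap_candidates(
                pw["start"].to_numpy(), pw["end"].to_numpy(), qs, qe
            )
            if len(cand) == 0:
                continue
            partner_sox2 = (
                bool(sox2.overlaps(chrom, ps, pe_)[0]) if sox2 is not None else False
            )
            for ci in cand:
                gene = pw.at[int(ci), "gene_id"]
                if pcat == "P":
                    n_prom[gene] += 1
                else:
                    n_enh[gene] += 1
                    if partner_sox2:
                        sox2_pe[gene] = True

    genes = genome.genes
    out = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "n_enhancer_partners": [n_enh[g] for g in genes["gene_id"]],
            "n_promoter_partners": [n_prom[g] for g in genes["gene_id"]],
            "has_sox2_pe": [sox2_pe[g] for g in genes["gene_id"]],
        }
    )
    out["category"] = np.where(
        out["n_enhancer_partners"] > 0,
        "has_pe",
        np.where(out["n_promoter_partners"] > 0, "pp_only", "not_connected"),
    )
    if sox2 is not None:
        pw_all = prom
        out["sox2_promoter"] = [
            bool(
                sox2.overlaps(
                    pw_all.at[i, "chrom"], pw_all.at[i, "start"], pw_all.at[i, "end"]
                )[0]
            )
            for i in pw_all.index
        ]
    else:
        out["sox2_promoter"] = False
    return out
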