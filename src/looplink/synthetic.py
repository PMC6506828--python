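"""Synthetic data generator with known ground truth.

Builds a small multi-chromosome genome, plants a regulatory architecture
(promoter- and enhancer-anchored chromatin loops, SOX2 and Pol II peaks,
histone-mark regions), and simulates the raw inputs every downstream stage
consumes: paired-end tag (PET) tables, peak BED sets, 200-bp bin-count
tracks, and replicate WT/MUT expression tables.

The defaults encode the study conditions the pipeline is meant to recover:
~87.5% of planted loops are promoter-mediated (split evenly between
promoter-promoter and promoter-enhancer), ~38.5% of distal anchors are
SOX2-bound, SOX2-bound distal anchors are almost always dual-marked
(H3K27ac + H3K4me1), and genes connected to SOX2-bound enhancers are
strongly downregulated in the mutant (to 15% of WT), on top of a smaller
genome-wide background of mild downregulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as llio
from .genome import Genome
from .intervals import ChromIntervals, merge_intervals

__all__ = [
    "EffectModel",
    "PlantedArchitecture",
    "SyntheticDataset",
    "make_genome",
    "make_architecture",
    "simulate_pets",
    "simulate_expression",
    "simulate_bin_counts",
    "make_dataset",
    "write_dataset",
    "read_dataset",
]

LOOP_COLUMNS = [
    "loop_id", "chrom", "a_start", "a_end", "b_start", "b_end",
    "intensity", "type_label", "gene_a", "gene_b", "enh_a", "enh_b",
]
ENHANCER_COLUMNS = ["enh_id", "chrom", "start", "end", "sox2_bound", "mark_state"]


def _place_nonoverlapping(rng, length, sizes, min_gap, lo=0):
    """Place len(sizes) intervals with pairwise gaps >= min_gap inside
    [lo, lo+length); returns start positions in random genomic order.
    Raises if the pieces do not fit."""
    sizes = np.asarray(sizes, dtype=np.int64)
    k = len(sizes)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    slack = length - int(sizes.sum()) - min_gap * (k - 1)
    if slack < 0:
        raise ValueError(
            "cannot place intervals without overlap at requested density"
        )
    cuts = np.sort(rng.uniform(0, slack, size=k)).astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(sizes[:-1] + min_gap)])
    return lo + cuts + offsets


def make_genome(
    seed: int,
    n_chroms: int = 2,
    chrom_length: int = 5_000_000,
    n_genes: int = 200,
    gene_length_range: tuple[int, int] = (5_000, 30_000),
    min_gene_gap: int = 5_000,
) -> Genome:
    """Deterministic toy genome: equal-length chromosomes, non-overlapping
    genes, one TSS per gene (gene start on +, last base on -)."""
    if n_chroms < 2:
        raise ValueError("need >=2 chromosomes so inter-chromosomal PETs can exist")
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if chrom_length < 1_000_000:
        raise ValueError("chrom_length must be >= 1e6")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    per_chrom = np.full(n_chroms, n_genes // n_chroms, dtype=int)
    per_chrom[: n_genes % n_chroms] += 1

    rows = []
    gid = 0
    for chrom, k in zip(chrom_names, per_chrom):
        sizes = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=k)
        starts = _place_nonoverlapping(rng, chrom_length, sizes, min_gene_gap)
        strands = rng.choice(["+", "-"], size=k)
        for s, size, strand in zip(starts, sizes, strands):
            gid += 1
            end = int(s + size)
            rows.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": chrom,
                    "start": int(s),
                    "end": end,
                    "strand": strand,
                    "tss": int(s) if strand == "+" else end - 1,
                }
            )
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    return Genome({c: int(chrom_length) for c in chrom_names}, genes)


@dataclass
class PlantedArchitecture:
    """Ground-truth regulatory architecture behind one synthetic dataset."""

    chrom_lengths: dict[str, int]
    loops: pd.DataFrame          # LOOP_COLUMNS
    enhancers: pd.DataFrame      # ENHANCER_COLUMNS
    sox2_peaks: pd.DataFrame     # chrom, start, end, name
    polII_peaks: pd.DataFrame
    k27_regions: pd.DataFrame
    k4me1_regions: pd.DataFrame
    gene_enhancers: pd.DataFrame  # gene_id, enh_id, sox2_bound
    truth_params: dict


def _assign_mark_state(rng, sox2_bound, p_active_sox2, nonsox2_state_probs):
    states = np.array(["active", "poised", "k27_only", "none"])
    n = len(sox2_bound)
    out = np.empty(n, dtype=object)
    u = rng.random(n)
    # SOX2-bound distal anchors are (nearly always) dual-marked
    sox = np.asarray(sox2_bound)
    out[sox & (u < p_active_sox2)] = "active"
    leftover = sox & (u >= p_active_sox2)
    out[leftover] = rng.choice(["poised", "k27_only"], size=int(leftover.sum()))
    probs = np.asarray(nonsox2_state_probs, dtype=float)
    out[~sox] = rng.choice(states, size=int((~sox).sum()), p=probs / probs.sum())
    return out


def make_architecture(
    genome: Genome,
    seed: int,
    n_loops: int = 400,
    frac_promoter_mediated: float = 0.875,
    frac_pp_within_promoter_mediated: float = 0.5,
    frac_distal_sox2: float = 0.385,
    frac_promoter_sox2: float = 0.15,
    p_active_given_sox2: float = 0.97,
    nonsox2_state_probs: tuple[float, float, float, float] = (0.70, 0.15, 0.075, 0.075),
    loop_intensity: float = 8.0,
    anchor_halfwidth: int = 600,
    enhancer_width: int = 1_500,
    min_anchor_sep: int = 4_000,
    tss_guard: int = 3_500,
    min_loop_span: int = 20_000,
) -> PlantedArchitecture:
    """Plant loops and regulatory elements on a genome.

    Loop types are drawn i.i.d. per loop: P-P with probability
    ``frac_promoter_mediated * frac_pp_within_promoter_mediated``, P-nonP
    with ``frac_promoter_mediated * (1 - frac_pp...)``, nonP-nonP
    otherwise. Distal (enhancer) anchors are placed at least ``tss_guard``
    bp from every TSS so that their loop anchors can never fall inside a
    +-2.5 kb promoter window.
    """
    for name, frac in [
        ("frac_promoter_mediated", frac_promoter_mediated),
        ("frac_pp_within_promoter_mediated", frac_pp_within_promoter_mediated),
        ("frac_distal_sox2", frac_distal_sox2),
        ("frac_promoter_sox2", frac_promoter_sox2),
    ]:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    if abs(sum(nonsox2_state_probs) - 1.0) > 1e-9:
        raise ValueError("nonsox2_state_probs must sum to 1")
    if n_loops < 20:
        raise ValueError("n_loops must be >= 20")
    if tss_guard < 2_500 + 1_000:
        raise ValueError("tss_guard must keep enhancers out of promoter windows")

    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)

    # loop types, i.i.d.
    u = rng.random(n_loops)
    p_pp = frac_promoter_mediated * frac_pp_within_promoter_mediated
    types = np.where(u < p_pp, "P-P",
                     np.where(u < frac_promoter_mediated, "P-nonP", "nonP-nonP"))

    # assign loops to chromosomes proportional to length
    loop_chrom = rng.choice(len(chroms), size=n_loops, p=lengths / lengths.sum())

    # how many distal anchors each chromosome needs
    need_enh = np.zeros(len(chroms), dtype=int)
    for ci, t in zip(loop_chrom, types):
        need_enh[ci] += {"P-P": 0, "P-nonP": 1, "nonP-nonP": 2}[t]

    # place enhancers inside TSS-guarded free space, chromosome by chromosome
    tss_by_chrom = genome.tss_by_chrom()
    enh_rows = []
    enh_pool: dict[int, list[int]] = {}
    eid = 0
    for ci, chrom in enumerate(chroms):
        k = int(need_enh[ci])
        enh_pool[ci] = []
        if k == 0:
            continue
        tss = tss_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        fs, fe = merge_intervals(tss - tss_guard, tss + tss_guard + 1, merge_touching=True)
        free = ChromIntervals({chrom: (fs, fe)}).complement({chrom: genome.chrom_lengths[chrom]})
        runs_s, runs_e = free.by_chrom[chrom]
        run_len = runs_e - runs_s
        unit = enhancer_width + min_anchor_sep
        capacity = np.maximum(0, (run_len - enhancer_width) // unit + 1)
        usable = capacity > 0
        if capacity.sum() < k:
            raise ValueError("not enough TSS-free space to place enhancers")
        alloc = rng.multivariate_hypergeometric(capacity[usable], k)
        for (rs, rl), a in zip(
            zip(runs_s[usable], run_len[usable]), alloc
        ):
            if a == 0:
                continue
            starts = _place_nonoverlapping(
                rng, int(rl), np.full(a, enhancer_width), min_anchor_sep, lo=int(rs)
            )
            for s in starts:
                eid += 1
                enh_rows.append((f"enh{eid:05d}", chrom, int(s), int(s + enhancer_width)))
                enh_pool[ci].append(eid - 1)
        rng.shuffle(enh_pool[ci])

    enh_df = pd.DataFrame(enh_rows, columns=["enh_id", "chrom", "start", "end"])
    sox2_bound = rng.random(len(enh_df)) < frac_distal_sox2
    enh_df["sox2_bound"] = sox2_bound
    enh_df["mark_state"] = _assign_mark_state(
        rng, sox2_bound, p_active_given_sox2, nonsox2_state_probs
    )

    genes = genome.genes
    gene_idx_by_chrom = {
        c: sub.index.to_numpy() for c, sub in genes.groupby("chrom", sort=False)
    }

    def pick_gene(chrom_i, near=None, tries=200):
        idx = gene_idx_by_chrom.get(chroms[chrom_i])
        if idx is None or len(idx) == 0:
            raise ValueError("no genes on chromosome required by planted loop")
        for _ in range(tries):
            gi = int(rng.choice(idx))
            if near is None or abs(int(genes.at[gi, "tss"]) - near) >= min_loop_span:
                return gi
        raise ValueError("could not satisfy loop-span constraint")

    loop_rows = []
    for li, (ci, t) in enumerate(zip(loop_chrom, types)):
        chrom = chroms[ci]
        if t == "P-P":
            g1 = pick_gene(ci)
            g2 = pick_gene(ci, near=int(genes.at[g1, "tss"]))
            t1, t2 = int(genes.at[g1, "tss"]), int(genes.at[g2, "tss"])
            ends = sorted(
                [
                    (t1 - anchor_halfwidth, t1 + anchor_halfwidth, genes.at[g1, "gene_id"], None),
                    (t2 - anchor_halfwidth, t2 + anchor_halfwidth, genes.at[g2, "gene_id"], None),
                ],
                key=lambda x: (x[0], x[1]),
            )
        elif t == "P-nonP":
            ei = enh_pool[ci].pop()
            e = enh_df.iloc[ei]
            mid = int((e["start"] + e["end"]) // 2)
            g1 = pick_gene(ci, near=mid)
            t1 = int(genes.at[g1, "tss"])
            ends = sorted(
                [
                    (t1 - anchor_halfwidth, t1 + anchor_halfwidth, genes.at[g1, "gene_id"], None),
                    (int(e["start"]), int(e["end"]), None, e["enh_id"]),
                ],
                key=lambda x: (x[0], x[1]),
            )
        else:  # nonP-nonP
            ei1 = enh_pool[ci].pop()
            e1 = enh_df.iloc[ei1]
            for _ in range(200):
                if not enh_pool[ci]:
                    raise ValueError("ran out of enhancers for nonP-nonP loops")
                ei2 = enh_pool[ci].pop()
                e2 = enh_df.iloc[ei2]
                if abs(int(e1["start"]) - int(e2["start"])) >= min_loop_span:
                    break
                enh_pool[ci].insert(0, ei2)  # retry with a different partner
            else:
                raise ValueError("could not satisfy loop-span constraint")
            ends = sorted(
                [
                    (int(e1["start"]), int(e1["end"]), None, e1["enh_id"]),
                    (int(e2["start"]), int(e2["end"]), None, e2["enh_id"]),
                ],
                key=lambda x: (x[0], x[1]),
            )
        (a_s, a_e, gene_a, enh_a), (b_s, b_e, gene_b, enh_b) = ends
        loop_rows.append(
            {
                "loop_id": f"loop{li + 1:05d}",
                "chrom": chrom,
                "a_start": int(a_s), "a_end": int(a_e),
                "b_start": int(b_s), "b_end": int(b_e),
                "intensity": float(loop_intensity),
                "type_label": t,
                "gene_a": gene_a, "gene_b": gene_b,
                "enh_a": enh_a, "enh_b": enh_b,
            }
        )
    loops = pd.DataFrame(loop_rows, columns=LOOP_COLUMNS)

    # peaks
    def centered_peaks(df, width, prefix, starts=None, ends=None):
        if len(df) == 0:
            return pd.DataFrame(columns=["chrom", "start", "end", "name"])
        s = df["start"].to_numpy() if starts is None else starts
        e = df["end"].to_numpy() if ends is None else ends
        mid = (s + e) // 2
        return pd.DataFrame(
            {
                "chrom": df["chrom"].to_numpy(),
                "start": mid - width // 2,
                "end": mid - width // 2 + width,
                "name": [f"{prefix}{i + 1}" for i in range(len(df))],
            }
        )

    sox2_enh = enh_df[enh_df["sox2_bound"]]
    prom_sox2_mask = rng.random(len(genes)) < frac_promoter_sox2
    prom_sox2 = genes[prom_sox2_mask]
    sox2_parts = [centered_peaks(sox2_enh, 200, "sox2_e")]
    if len(prom_sox2):
        sox2_parts.append(
            pd.DataFrame(
                {
                    "chrom": prom_sox2["chrom"].to_numpy(),
                    "start": prom_sox2["tss"].to_numpy() - 100,
                    "end": prom_sox2["tss"].to_numpy() + 100,
                    "name": ["sox2_p" + g for g in prom_sox2["gene_id"]],
                }
            )
        )
    sox2_peaks = pd.concat(sox2_parts, ignore_index=True)

    anchor_mids = np.concatenate(
        [
            (loops["a_start"].to_numpy() + loops["a_end"].to_numpy()) // 2,
            (loops["b_start"].to_numpy() + loops["b_end"].to_numpy()) // 2,
        ]
    )
    polII_peaks = pd.DataFrame(
        {
            "chrom": np.concatenate([loops["chrom"].to_numpy()] * 2),
            "start": anchor_mids - 150,
            "end": anchor_mids + 150,
            "name": [f"polII{i + 1}" for i in range(2 * len(loops))],
        }
    )
    tss_peaks = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": genes["tss"].to_numpy() - 150,
            "end": genes["tss"].to_numpy() + 150,
            "name": ["polII_p" + g for g in genes["gene_id"]],
        }
    )
    polII_peaks = pd.concat([polII_peaks, tss_peaks], ignore_index=True)

    k27_enh = enh_df[enh_df["mark_state"].isin(["active", "k27_only"])]
    k4_enh = enh_df[enh_df["mark_state"].isin(["active", "poised"])]
    prom_marks = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": genes["tss"].to_numpy() - 500,
            "end": genes["tss"].to_numpy() + 500,
            "name": ["mark_p" + g for g in genes["gene_id"]],
        }
    )
    k27_regions = pd.concat(
        [centered_peaks(k27_enh, 600, "k27_e"), prom_marks], ignore_index=True
    )
    k4me1_regions = pd.concat(
        [centered_peaks(k4_enh, 600, "k4_e"), prom_marks], ignore_index=True
    )

    # gene-enhancer connectivity implied by P-nonP loops
    ge_rows = []
    for _, row in loops[loops["type_label"] == "P-nonP"].iterrows():
        gene = row["gene_a"] if row["gene_a"] is not None else row["gene_b"]
        enh = row["enh_a"] if row["enh_a"] is not None else row["enh_b"]
        sox = bool(enh_df.loc[enh_df["enh_id"] == enh, "sox2_bound"].iloc[0])
        ge_rows.append({"gene_id": gene, "enh_id": enh, "sox2_bound": sox})
    gene_enhancers = pd.DataFrame(ge_rows, columns=["gene_id", "enh_id", "sox2_bound"])

    realized = pd.Series(types).value_counts().to_dict()
    truth_params = {
        "seed": int(seed),
        "n_loops": int(n_loops),
        "frac_promoter_mediated": frac_promoter_mediated,
        "frac_pp_within_promoter_mediated": frac_pp_within_promoter_mediated,
        "frac_distal_sox2": frac_distal_sox2,
        "frac_promoter_sox2": frac_promoter_sox2,
        "p_active_given_sox2": p_active_given_sox2,
        "loop_intensity": loop_intensity,
        "realized_type_counts": {k: int(v) for k, v in realized.items()},
    }

    arch = PlantedArchitecture(
        chrom_lengths=dict(genome.chrom_lengths),
        loops=loops,
        enhancers=enh_df[ENHANCER_COLUMNS],
        sox2_peaks=sox2_peaks,
        polII_peaks=polII_peaks,
        k27_regions=k27_regions,
        k4me1_regions=k4me1_regions,
        gene_enhancers=gene_enhancers,
        truth_params=truth_params,
    )
    _check_architecture(arch, genome)
    return arch


def _check_architecture(arch: PlantedArchitecture, genome: Genome) -> None:
    """Planted labels must be consistent with anchor geometry."""
    prom = ChromIntervals.from_frame(genome.promoter_windows(2_500))
    loops = arch.loops
    for side in ("a", "b"):
        is_p = prom.overlaps_frame(
            loops.rename(columns={f"{side}_start": "start", f"{side}_end": "end"}),
        )
        has_gene = loops[f"gene_{side}"].notna().to_numpy()
        if not np.array_equal(is_p, has_gene):
            raise AssertionError("planted loop type inconsistent with anchor geometry")


def _sample_powerlaw(rng, n, exponent, dmin, dmax):
    """Distances with pdf ~ d^-exponent on [dmin, dmax]."""
    u = rng.random(n)
    if abs(exponent - 1.0) < 1e-12:
        return np.exp(u * (np.log(dmax) - np.log(dmin)) + np.log(dmin)).astype(np.int64)
    a = 1.0 - exponent
    return ((u * (dmax**a - dmin**a) + dmin**a) ** (1.0 / a)).astype(np.int64)


def simulate_pets(
    arch: PlantedArchitecture,
    seed: int,
    n_signal_pets: int | None = None,
    n_background_pets: int = 0,
    background_mix: tuple[float, float, float] = (0.30, 0.55, 0.15),
    duplicate_rate: float = 0.0,
    chimera_rate: float = 0.0,
    self_span: int = 8_000,
    background_distance: str = "powerlaw",
    powerlaw_exponent: float = 1.0,
) -> pd.DataFrame:
    """Simulate PET tag pairs: loop signal plus self/intra/inter background.

    ``n_signal_pets=None`` draws each loop's PET count from
    Poisson(intensity); an integer distributes exactly that many signal
    PETs across loops proportional to intensity. ``background_distance``
    selects the intra-chromosomal background distance law: a truncated
    power law (heavy-tailed ligation noise) or ``"uniform"`` (both tags
    independently uniform, the re-pairing-invariant null).
    """
    if abs(sum(background_mix) - 1.0) > 1e-9:
        raise ValueError("background_mix must sum to 1")
    if not (0.0 <= duplicate_rate < 1.0 and 0.0 <= chimera_rate <= 1.0):
        raise ValueError("rates out of range")
    rng = np.random.default_rng(seed)
    chroms = list(arch.chrom_lengths)
    lengths = np.array([arch.chrom_lengths[c] for c in chroms], dtype=np.int64)

    parts = []
    loops = arch.loops
    if len(loops):
        inten = loops["intensity"].to_numpy(dtype=float)
        if n_signal_pets is None:
            per_loop = rng.poisson(inten)
        else:
            per_loop = rng.multinomial(int(n_signal_pets), inten / inten.sum())
        for (_, row), k in zip(loops.iterrows(), per_loop):
            if k == 0:
                continue
            pa = rng.integers(row["a_start"], row["a_end"], size=k)
            pb = rng.integers(row["b_start"], row["b_end"], size=k)
            parts.append(
                pd.DataFrame(
                    {"chrom_a": row["chrom"], "pos_a": pa,
                     "chrom_b": row["chrom"], "pos_b": pb}
                )
            )

    n_self, n_intra, n_inter = rng.multinomial(int(n_background_pets), background_mix)

    if n_self:
        ci = rng.choice(len(chroms), size=n_self, p=lengths / lengths.sum())
        pa = (rng.random(n_self) * (lengths[ci] - self_span - 1)).astype(np.int64)
        span = rng.integers(0, self_span + 1, size=n_self)
        parts.append(
            pd.DataFrame(
                {"chrom_a": np.array(chroms)[ci], "pos_a": pa,
                 "chrom_b": np.array(chroms)[ci], "pos_b": pa + span}
            )
        )

    if n_intra:
        ci = rng.choice(len(chroms), size=n_intra, p=lengths / lengths.sum())
        if background_distance == "powerlaw":
            d = _sample_powerlaw(rng, n_intra, powerlaw_exponent,
                                 self_span + 1, lengths[ci] // 2)
            pa = (rng.random(n_intra) * (lengths[ci] - d)).astype(np.int64)
            pb = pa + d
        elif background_distance == "uniform":
            pa = (rng.random(n_intra) * lengths[ci]).astype(np.int64)
            pb = (rng.random(n_intra) * lengths[ci]).astype(np.int64)
            bad = np.abs(pa - pb) <= self_span
            while bad.any():
                pb[bad] = (rng.random(int(bad.sum())) * lengths[ci][bad]).astype(np.int64)
                bad = np.abs(pa - pb) <= self_span
            lo = np.minimum(pa, pb)
            pb = np.maximum(pa, pb)
            pa = lo
        else:
            raise ValueError(f"unknown background_distance {background_distance!r}")
        parts.append(
            pd.DataFrame(
                {"chrom_a": np.array(chroms)[ci], "pos_a": pa,
                 "chrom_b": np.array(chroms)[ci], "pos_b": pb}
            )
        )

    if n_inter:
        c1 = rng.choice(len(chroms), size=n_inter)
        shift = rng.integers(1, len(chroms), size=n_inter)
        c2 = (c1 + shift) % len(chroms)
        p1 = (rng.random(n_inter) * lengths[c1]).astype(np.int64)
        p2 = (rng.random(n_inter) * lengths[c2]).astype(np.int64)
        parts.append(
            pd.DataFrame(
                {"chrom_a": np.array(chroms)[c1], "pos_a": p1,
                 "chrom_b": np.array(chroms)[c2], "pos_b": p2}
            )
        )

    if parts:
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["chrom_a", "pos_a", "chrom_b", "pos_b"])
    n = len(df)
    df["strand_a"] = rng.choice(["+", "-"], size=n)
    df["strand_b"] = rng.choice(["+", "-"], size=n)

    chim = rng.random(n) < chimera_rate
    half = rng.choice(["A", "B"], size=n)
    df["linker_a"] = half
    df["linker_b"] = np.where(chim, np.where(half == "A", "B", "A"), half)

    # clonal PCR duplicates: near-exact copies of existing PETs
    n_dup = int(round(duplicate_rate * n))
    if n_dup:
        src = rng.integers(0, n, size=n_dup)
        dup = df.iloc[src].copy().reset_index(drop=True)
        dup["pos_a"] = np.maximum(dup["pos_a"] + rng.integers(-2, 3, size=n_dup), 0)
        dup["pos_b"] = np.maximum(dup["pos_b"] + rng.integers(-2, 3, size=n_dup), 0)
        df = pd.concat([df, dup], ignore_index=True)

    # canonical tag order, then shuffle row order
    swap = (df["chrom_a"] > df["chrom_b"]) | (
        (df["chrom_a"] == df["chrom_b"]) & (df["pos_a"] > df["pos_b"])
    )
    for a, b in [("chrom_a", "chrom_b"), ("pos_a", "pos_b"), ("strand_a", "strand_b")]:
        va, vb = df[a].copy(), df[b].copy()
        df.loc[swap, a] = vb[swap]
        df.loc[swap, b] = va[swap]
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["pos_a"] = df["pos_a"].astype(np.int64)
    df["pos_b"] = df["pos_b"].astype(np.int64)
    return df[llio.TAGPAIR_COLUMNS]


@dataclass
class EffectModel:
    """Expression model tying planted connectivity to WT/MUT TPM tables.

    WT mean TPM = lognormal base draw x per_enhancer_boost^(connected
    enhancers). MUT mean = WT x mut_downregulation_factor for genes with
    >=1 SOX2-bound connected enhancer; an independent background fraction
    of the remaining genes is mildly downregulated (global effect of the
    perturbation); all other genes are unchanged. Replicates get
    mean-preserving lognormal noise at the stated coefficient of
    variation.
    """

    base_log_tpm_mean: float = 3.4     # ln scale; median ~30 TPM
    base_log_tpm_sigma: float = 1.2
    per_enhancer_boost: float = 1.5
    mut_downregulation_factor: float = 0.15
    background_down_fraction: float = 0.08
    background_down_factor: float = 0.5
    replicate_noise_cv: float = 0.2
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_enhancer_boost", "mut_downregulation_factor",
                     "background_down_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mut_downregulation_factor > 1:
            raise ValueError("mut_downregulation_factor must be <= 1")
        if self.n_replicates < 1:
            raise ValueError("need >=1 replicate")


def simulate_expression(
    arch: PlantedArchitecture, genome: Genome, model: EffectModel
) -> pd.DataFrame:
    """Per-gene TPM replicate table with ground-truth labels attached."""
    rng = np.random.default_rng(model.seed)
    genes = genome.genes
    n = len(genes)

    conn = arch.gene_enhancers.groupby("gene_id").agg(
        n_enhancers=("enh_id", "size"), has_sox2=("sox2_bound", "any")
    )
    conn_full = conn.reindex(genes["gene_id"])
    n_enh = conn_full["n_enhancers"].fillna(0).to_numpy(dtype=np.int64)
    has_sox2 = conn_full["has_sox2"].eq(True).to_numpy(dtype=bool)

    base = np.exp(rng.normal(model.base_log_tpm_mean, model.base_log_tpm_sigma, size=n))
    wt_mean = base * model.per_enhancer_boost ** n_enh

    planted_down = has_sox2 & (model.mut_downregulation_factor < 1.0)
    bg_down = (~has_sox2) & (rng.random(n) < model.background_down_fraction)
    factor = np.ones(n)
    factor[has_sox2] = model.mut_downregulation_factor
    factor[bg_down] = model.background_down_factor
    mut_mean = wt_mean * factor

    cv = model.replicate_noise_cv
    sigma = np.sqrt(np.log1p(cv * cv))

    def reps(means):
        if cv == 0:
            return np.tile(means[:, None], (1, model.n_replicates))
        noise = rng.normal(-sigma * sigma / 2.0, sigma, size=(n, model.n_replicates))
        return means[:, None] * np.exp(noise)

    wt = reps(wt_mean)
    mut = reps(mut_mean)

    out = {"gene_id": genes["gene_id"].to_numpy()}
    for r in range(model.n_replicates):
        out[f"tpm_wt_rep{r + 1}"] = wt[:, r]
    for r in range(model.n_replicates):
        out[f"tpm_mut_rep{r + 1}"] = mut[:, r]
    df = pd.DataFrame(out)
    df["true_wt_mean"] = wt_mean
    df["true_mut_mean"] = mut_mean
    df["n_enhancers"] = n_enh
    df["has_sox2_enhancer"] = has_sox2
    df["planted_down"] = planted_down
    df["background_down"] = bg_down
    return df


def simulate_bin_counts(
    arch: PlantedArchitecture,
    seed: int,
    bin_size: int = 200,
    background_rate: float = 0.4,
    mark_rate: float = 8.0,
    mut_k27_loss_factor: float = 0.15,
) -> dict:
    """Poisson read counts per 200-bp bin for each mark and condition.

    Bins inside a mark region get an elevated rate; in MUT, H3K27ac over
    SOX2-bound enhancers is reduced by ``mut_k27_loss_factor``
    (decommissioning of SOX2-dependent enhancers), creating true
    differential bins with a known location.
    """
    rng = np.random.default_rng(seed)
    sox2_enh = ChromIntervals.from_frame(arch.enhancers[arch.enhancers["sox2_bound"]])
    marks = {"H3K27ac": arch.k27_regions, "H3K4me1": arch.k4me1_regions}
    tracks: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for mark, regions in marks.items():
        idx = ChromIntervals.from_frame(regions)
        for cond in ("wt", "mut"):
            per_chrom = {}
            for chrom, length in arch.chrom_lengths.items():
                n_bins = (length + bin_size - 1) // bin_size
                lam = np.full(n_bins, background_rate)
                if chrom in idx.by_chrom:
                    s, e = idx.by_chrom[chrom]
                    for rs, re_ in zip(s, e):
                        b0, b1 = rs // bin_size, (re_ + bin_size - 1) // bin_size
                        rate = mark_rate
                        if (
                            cond == "mut"
                            and mark == "H3K27ac"
                            and sox2_enh.overlaps(chrom, rs, re_)[0]
                        ):
                            rate = mark_rate * mut_k27_loss_factor
                        lam[b0:b1] += rate
                per_chrom[chrom] = rng.poisson(lam).astype(np.int64)
            tracks[(mark, cond)] = per_chrom
    return {"bin_size": bin_size, "tracks": tracks}


@dataclass
class SyntheticDataset:
    genome: Genome
    arch: PlantedArchitecture
    pets: pd.DataFrame
    expression: pd.DataFrame
    bins: dict
    params: dict


def make_dataset(
    seed: int,
    genome_kwargs: dict | None = None,
    arch_kwargs: dict | None = None,
    pet_kwargs: dict | None = None,
    effect_kwargs: dict | None = None,
    bin_kwargs: dict | None = None,
) -> SyntheticDataset:
    """One-call dataset: sub-stage seeds are derived from ``seed`` so each
    component is independently reproducible."""
    genome_kwargs = dict(genome_kwargs or {})
    arch_kwargs = dict(arch_kwargs or {})
    pet_kwargs = dict(pet_kwargs or {})
    effect_kwargs = dict(effect_kwargs or {})
    bin_kwargs = dict(bin_kwargs or {})
    sub = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]
    genome = make_genome(seeds[0], **genome_kwargs)
    arch = make_architecture(genome, seeds[1], **arch_kwargs)
    pet_kwargs.setdefault("n_background_pets", 5_000)
    pets = simulate_pets(arch, seeds[2], **pet_kwargs)
    model = EffectModel(seed=seeds[3], **effect_kwargs)
    expression = simulate_expression(arch, genome, model)
    bins = simulate_bin_counts(arch, seeds[4], **bin_kwargs)
    params = {
        "seed": int(seed),
        "stage_seeds": seeds,
        "genome": genome_kwargs,
        "architecture": arch_kwargs,
        "pets": {k: v for k, v in pet_kwargs.items() if not isinstance(v, np.ndarray)},
        "effect_model": asdict(model),
        "bins": bin_kwargs,
    }
    return SyntheticDataset(genome, arch, pets, expression, bins, params)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _check_bed_bounds(ds)
    llio.write_tagpairs(ds.pets, out / "pets.tsv")
    llio.write_bed(ds.arch.sox2_peaks, out / "sox2_peaks.bed")
    llio.write_bed(ds.arch.polII_peaks, out / "polII_peaks.bed")
    llio.write_bed(ds.arch.k27_regions, out / "h3k27ac_peaks.bed")
    llio.write_bed(ds.arch.k4me1_regions, out / "h3k4me1_peaks.bed")
    llio.write_genes_bed12(ds.genome.genes, out / "genes.bed12")
    llio.write_genes_tsv(ds.genome.genes, out / "genes.tsv")
    expr_cols = ["gene_id"] + [c for c in ds.expression.columns if c.startswith("tpm_")]
    llio.write_expression(ds.expression[expr_cols], out / "expression.tsv")
    for (mark, cond), track in ds.bins["tracks"].items():
        llio.write_bedgraph(track, ds.bins["bin_size"],
                            out / f"bins_{mark}_{cond}.bedGraph")
    truth = {
        "params": ds.params,
        "chrom_lengths": ds.arch.chrom_lengths,
        "bin_size": ds.bins["bin_size"],
        "loops": ds.arch.loops,
        "enhancers": ds.arch.enhancers,
        "gene_enhancers": ds.arch.gene_enhancers,
        "truth_params": ds.arch.truth_params,
        "expression_truth": ds.expression[
            ["gene_id", "true_wt_mean", "true_mut_mean", "n_enhancers",
             "has_sox2_enhancer", "planted_down", "background_down"]
        ],
    }
    llio.write_json(truth, out / "truth.json")


def _check_bed_bounds(ds: SyntheticDataset) -> None:
    for df in (ds.arch.sox2_peaks, ds.arch.polII_peaks,
               ds.arch.k27_regions, ds.arch.k4me1_regions):
        lengths = df["chrom"].map(ds.arch.chrom_lengths)
        if ((df["start"] < 0) | (df["start"] >= df["end"]) | (df["end"] > lengths)).any():
            raise AssertionError("peak interval violates 0 <= start < end <= chrom length")


def read_dataset(outdir) -> SyntheticDataset:
    """Re-read a written dataset; frames round-trip exactly."""
    out = Path(outdir)
    truth = llio.read_json(out / "truth.json")
    genes = llio.read_genes_tsv(out / "genes.tsv")
    chrom_lengths = {k: int(v) for k, v in truth["chrom_lengths"].items()}
    genome = Genome(chrom_lengths, genes)
    loops = pd.DataFrame(truth["loops"], columns=LOOP_COLUMNS)
    enhancers = pd.DataFrame(truth["enhancers"], columns=ENHANCER_COLUMNS)
    gene_enh = pd.DataFrame(truth["gene_enhancers"],
                            columns=["gene_id", "enh_id", "sox2_bound"])
    arch = PlantedArchitecture(
        chrom_lengths=chrom_lengths,
        loops=loops,
        enhancers=enhancers,
        sox2_peaks=llio.read_bed(out / "sox2_peaks.bed"),
        polII_peaks=llio.read_bed(out / "polII_peaks.bed"),
        k27_regions=llio.read_bed(out / "h3k27ac_peaks.bed"),
        k4me1_regions=llio.read_bed(out / "h3k4me1_peaks.bed"),
        gene_enhancers=gene_enh,
        truth_params=truth["truth_params"],
    )
    pets = llio.read_tagpairs(out / "pets.tsv")
    expression = llio.read_expression(out / "expression.tsv")
    etruth = pd.DataFrame(truth["expression_truth"])
    expression = expression.merge(etruth, on="gene_id", how="left")
    bin_size = int(truth["bin_size"])
    tracks = {}
    for mark in ("H3K27ac", "H3K4me1"):
        for cond in ("wt", "mut"):
            path = out / f"bins_{mark}_{cond}.bedGraph"
            if path.exists():
                tracks[(mark, cond)] = llio.read_bedgraph(path, bin_size)
    bins = {"bin_size": bin_size, "tracks": tracks}
    return SyntheticDataset(genome, arch, pets, expression, bins, truth["params"])
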