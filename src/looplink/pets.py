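"""PET classification, deduplication, clustering, and loop significance.

The statistical core: intra-chromosomal PETs whose respective ends fall
within an extension window (default 1 kb) are single-linkage clustered
into candidate interactions; each cluster's iPET count c is scored with a
hypergeometric tail against the anchors' marginal tag counts and the
library depth, adjusted by Benjamini-Hochberg, and thresholded on iPET
count, FDR and raw p.

Two protocol dialects are supported: ``tr1`` (half-linker barcodes,
iPET >= 2) and ``insitu`` (bridge linker, iPET >= 3); both share the
8-kb self-ligation span and 1-kb clustering extension.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterParams",
    "classify_linker",
    "classify_pets",
    "deduplicate",
    "cluster_intra_pets",
    "hypergeom_pvalue",
    "bh_fdr",
    "attach_cluster_stats",
    "call_significant",
    "shuffle_noise",
    "loops_per_million",
]

CHIMERIC = "chimeric"
SELF_LIGATION = "self_ligation"
INTRA = "intra_chromosomal"
INTER = "inter_chromosomal"


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for one protocol dialect (defaults: in-situ)."""

    self_span: int = 8_000
    extension: int = 1_000
    dedup_tolerance: int = 2
    min_ipet: int = 3
    fdr_cutoff: float = 0.05
    p_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if self.min_ipet < 2:
            raise ValueError("min_ipet must be >= 2")
        if min(self.self_span, self.extension, self.dedup_tolerance) < 0:
            raise ValueError("spans and tolerances must be non-negative")

    @classmethod
    def for_dialect(cls, dialect: str) -> "ClusterParams":
        if dialect == "tr1":
            return cls(min_ipet=2)
        if dialect == "insitu":
            return cls(min_ipet=3)
        raise ValueError(f"unknown dialect {dialect!r}")


def classify_linker(linker_a, linker_b) -> str:
    """AA/BB full linkers are intra-molecular (non-chimeric); AB/BA are
    inter-molecular ligation noise. Absent linkers (bridge-linker
    protocol) are non-chimeric by construction."""
    if linker_a is None and linker_b is None:
        return "non_chimeric"
    if linker_a in ("A", "B") and linker_b in ("A", "B"):
        return "non_chimeric" if linker_a == linker_b else CHIMERIC
    raise ValueError(f"unknown linker codes ({linker_a!r}, {linker_b!r})")


def classify_pets(pets: pd.DataFrame, self_span: int = 8_000) -> pd.Series:
    """Vectorised class per PET: chimeric (by linker) beats everything;
    then inter-chromosomal, self-ligation (distance <= self_span,
    inclusive), or intra-chromosomal."""
    la = pets["linker_a"] if "linker_a" in pets.columns else pd.Series([None] * len(pets))
    lb = pets["linker_b"] if "linker_b" in pets.columns else pd.Series([None] * len(pets))
    la = la.where(pd.notna(la), None).to_numpy(dtype=object)
    lb = lb.where(pd.notna(lb), None).to_numpy(dtype=object)
    known = {"A", "B", None}
    bad = [x for x in set(la) | set(lb) if x not in known]
    if bad:
        raise ValueError(f"unknown linker codes {bad}")
    chim = np.array(
        [a is not None and b is not None and a != b for a, b in zip(la, lb)]
    )
    same = (pets["chrom_a"] == pets["chrom_b"]).to_numpy()
    dist = np.abs(pets["pos_a"].to_numpy() - pets["pos_b"].to_numpy())
    cls = np.where(~same, INTER, np.where(dist <= self_span, SELF_LIGATION, INTRA))
    cls = np.where(chim, CHIMERIC, cls)
    return pd.Series(cls, index=pets.index, name="pet_class")


def classify_pet(pet, self_span: int = 8_000) -> str:
    """Single-PET convenience wrapper (pet: mapping with chrom/pos keys)."""
    if pet["chrom_a"] != pet["chrom_b"]:
        return INTER
    d = abs(int(pet["pos_a"]) - int(pet["pos_b"]))
    return SELF_LIGATION if d <= self_span else INTRA


def deduplicate(pets: pd.DataFrame, tolerance: int = 2) -> pd.DataFrame:
    """Collapse clonal PCR duplicates.

    Two PETs are duplicates when both ends lie within ``tolerance`` bp
    (jointly). Greedy scan in (chrom_a, chrom_b, pos_a, pos_b) sort order
    keeps the lexicographically smallest member of each group, which makes
    the result independent of input order.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if len(pets) == 0:
        return pets.copy()
    df = pets.sort_values(
        ["chrom_a", "chrom_b", "pos_a", "pos_b"], kind="mergesort"
    )
    keep_idx = []
    for _, sub in df.groupby(["chrom_a", "chrom_b"], sort=False):
        pa = sub["pos_a"].to_numpy()
        pb = sub["pos_b"].to_numpy()
        idx = sub.index.to_numpy()
        kept_a: list[int] = []
        kept_b: list[int] = []
        lo = 0
        for i in range(len(sub)):
            while lo < len(kept_a) and kept_a[lo] < pa[i] - tolerance:
                lo += 1
            dup = any(
                abs(kept_b[j] - pb[i]) <= tolerance
                for j in range(lo, len(kept_a))
                if abs(kept_a[j] - pa[i]) <= tolerance
            )
            if not dup:
                kept_a.append(int(pa[i]))
                kept_b.append(int(pb[i]))
                keep_idx.append(idx[i])
    return df.loc[df.index.isin(keep_idx)].sort_index()


def _left_window_pairs(pos: np.ndarray, extension: int):
    """Candidate (i, j) index pairs, i<j, with pos[j]-pos[i] <= extension;
    pos must be sorted ascending."""
    n = len(pos)
    hi = np.searchsorted(pos, pos + extension, side="right")
    idx = np.arange(n)
    counts = hi - idx - 1
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    i_rep = np.repeat(idx, counts)
    cum = np.concatenate([[0], np.cumsum(counts)])
    j_rep = np.arange(total) - np.repeat(cum[:-1], counts) + i_rep + 1
    return i_rep, j_rep


def cluster_intra_pets(
    pets: pd.DataFrame, extension: int = 1_000
) -> pd.DataFrame:
    """Single-linkage clustering of intra-chromosomal PETs.

    Two PETs join one cluster iff their left ends are within ``extension``
    AND their right ends are within ``extension`` (transitively closed).
    Anchors span member tag positions, [min, max+1) per side. Singleton
    clusters are discarded as noise. Output is sorted by (chrom, a_start,
    b_start) and independent of input order.
    """
    cols = ["chrom", "a_start", "a_end", "b_start", "b_end", "c"]
    if len(pets) == 0:
        return pd.DataFrame(columns=cols)
    if (pets["chrom_a"] != pets["chrom_b"]).any():
        raise ValueError("cluster_intra_pets expects intra-chromosomal PETs only")
    rows = []
    for chrom, sub in pets.groupby("chrom_a", sort=True):
        order = np.lexsort((sub["pos_b"].to_numpy(), sub["pos_a"].to_numpy()))
        pa = sub["pos_a"].to_numpy()[order]
        pb = sub["pos_b"].to_numpy()[order]
        n = len(pa)
        i_rep, j_rep = _left_window_pairs(pa, extension)
        edge = np.abs(pb[i_rep] - pb[j_rep]) <= extension
        g = sparse.coo_matrix(
            (np.ones(int(edge.sum())), (i_rep[edge], j_rep[edge])), shape=(n, n)
        )
        _, labels = connected_components(g, directed=False)
        df = pd.DataFrame({"label": labels, "pa": pa, "pb": pb})
        agg = df.groupby("label").agg(
            a_start=("pa", "min"), a_max=("pa", "max"),
            b_start=("pb", "min"), b_max=("pb", "max"),
            c=("pa", "size"),
        )
        agg = agg[agg["c"] >= 2]
        for _, r in agg.iterrows():
            rows.append(
                {
                    "chrom": chrom,
                    "a_start": int(r["a_start"]), "a_end": int(r["a_max"]) + 1,
                    "b_start": int(r["b_start"]), "b_end": int(r["b_max"]) + 1,
                    "c": int(r["c"]),
                }
            )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "a_start", "b_start"]).reset_index(drop=True)


def hypergeom_pvalue(c: int, n_a: int, n_b: int, T: int) -> float:
    """Upper-tail hypergeometric p = P(X >= c) for a cluster of c iPETs
    whose anchors carry n_a and n_b tags out of T intra-chromosomal PETs.
    Symmetric in (n_a, n_b)."""
    if not (0 <= c <= min(n_a, n_b) and n_a <= T and n_b <= T):
        raise ValueError(f"invalid hypergeometric arguments c={c}, n_a={n_a}, n_b={n_b}, T={T}")
    if c == 0:
        return 1.0
    p = float(hypergeom.sf(c - 1, T, n_a, n_b))
    return min(max(p, 0.0), 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tag_index(pets: pd.DataFrame) -> dict[str, np.ndarray]:
    """All tag end positions per chromosome, sorted (both PET sides)."""
    tags: dict[str, list[np.ndarray]] = {}
    for side in ("a", "b"):
        for chrom, sub in pets.groupby(f"chrom_{side}", sort=False):
            tags.setdefault(str(chrom), []).append(sub[f"pos_{side}"].to_numpy())
    return {c: np.sort(np.concatenate(v)) for c, v in tags.items()}


def attach_cluster_stats(
    clusters: pd.DataFrame, intra_pets: pd.DataFrame
) -> pd.DataFrame:
    """Add n_a, n_b, p, q columns. The population T is the number of
    deduplicated intra-chromosomal PETs; anchor tag counts include both
    PET sides."""
    out = clusters.copy()
    if len(out) == 0:
        for col in ("n_a", "n_b", "p", "q"):
            out[col] = np.array([], dtype=float)
        return out
    T = len(intra_pets)
    tags = _tag_index(intra_pets)
    n_a = np.zeros(len(out), dtype=np.int64)
    n_b = np.zeros(len(out), dtype=np.int64)
    for chrom, sub in out.groupby("chrom", sort=False):
        pos = tags.get(str(chrom), np.empty(0, dtype=np.int64))
        m = out["chrom"].to_numpy() == chrom
        for side, arr in (("a", n_a), ("b", n_b)):
            lo = np.searchsorted(pos, sub[f"{side}_start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, sub[f"{side}_end"].to_numpy(), side="left")
            arr[m] = hi - lo
    # tag counts are capped at T so the urn model stays well-posed
    n_a = np.minimum(n_a, T)
    n_b = np.minimum(n_b, T)
    out["n_a"] = n_a
    out["n_b"] = n_b
    out["p"] = [
        hypergeom_pvalue(min(int(c), int(na), int(nb)), int(na), int(nb), T)
        for c, na, nb in zip(out["c"], n_a, n_b)
    ]
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def call_significant(
    clusters: pd.DataFrame, params: ClusterParams = ClusterParams()
) -> pd.DataFrame:
    """Flag clusters passing iPET, FDR, and raw-p thresholds."""
    out = clusters.copy()
    out["significant"] = (
        (out["c"] >= params.min_ipet)
        & (out["q"] < params.fdr_cutoff)
        & (out["p"] < params.p_cutoff)
    )
    return out


def call_loops(
    pets: pd.DataFrame, params: ClusterParams = ClusterParams()
) -> dict:
    """Full calling pipeline from a raw tag-pair table.

    Returns a dict with the classified counts, deduplicated PET table,
    clusters (with statistics and significance flags), and the
    significant-loop table.
    """
    cls = classify_pets(pets, params.self_span)
    non_chim = pets[cls != CHIMERIC]
    unique = deduplicate(non_chim, params.dedup_tolerance)
    ucls = classify_pets(unique, params.self_span)
    intra = unique[ucls == INTRA]
    clusters = cluster_intra_pets(intra, params.extension)
    clusters = attach_cluster_stats(clusters, intra)
    clusters = call_significant(clusters, params)
    return {
        "n_total": int(len(pets)),
        "n_chimeric": int((cls == CHIMERIC).sum()),
        "n_non_chimeric": int(len(non_chim)),
        "n_unique": int(len(unique)),
        "n_self": int((ucls == SELF_LIGATION).sum()),
        "n_intra": int(len(intra)),
        "n_inter": int((ucls == INTER).sum()),
        "unique_pets": unique,
        "intra_pets": intra,
        "clusters": clusters,
        "significant": clusters[clusters["significant"]].reset_index(drop=True),
    }


def shuffle_noise(
    intra_pets: pd.DataFrame,
    n_iterations: int = 20,
    seed: int = 0,
    params: ClusterParams = ClusterParams(),
) -> float:
    """Noise level from random tag re-pairing.

    Per iteration, left and right tags are re-paired uniformly at random
    within each chromosome, re-paired PETs falling within the
    self-ligation span are dropped, the rest re-clustered, and clusters of
    2+ PETs counted. Returns mean simulated count / real count.
    """
    real = len(cluster_intra_pets(intra_pets, params.extension))
    if real == 0:
        raise ValueError("no real PET-2+ clusters; noise ratio undefined")
    rng = np.random.default_rng(seed)
    sim_counts = []
    for _ in range(n_iterations):
        parts = []
        for chrom, sub in intra_pets.groupby("chrom_a", sort=True):
            pa = sub["pos_a"].to_numpy()
            pb = rng.permutation(sub["pos_b"].to_numpy())
            lo = np.minimum(pa, pb)
            hi = np.maximum(pa, pb)
            keep = hi - lo > params.self_span
            parts.append(
                pd.DataFrame(
                    {"chrom_a": chrom, "pos_a": lo[keep],
                     "chrom_b": chrom, "pos_b": hi[keep]}
                )
            )
        sim = pd.concat(parts, ignore_index=True)
        sim_counts.append(len(cluster_intra_pets(sim, params.extension)))
    return float(np.mean(sim_counts)) / real


def loops_per_million(n_loops: int, n_intra_pets: int) -> int:
    """Significant loops per million intra-chromosomal PETs, rounded to
    the nearest integer, half away from zero."""
    if n_intra_pets <= 0:
        raise ValueError("n_intra_pets must be > 0")
    x = n_loops / n_intra_pets * 1_000_000
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
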