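"""Signed Fisher co-association scores between gene sets.

For an expression-variation group of size n and an interaction category
of size m among N eligible genes with k genes in common, a Fisher exact
test on [[k, n-k], [m-k, N-n-m+k]] gives p; the co-association score is
-log10(p) when k exceeds the independence expectation n*m/N and
+log10(p) (non-positive) otherwise. |score| > 2 is the conventional
significance line.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapCounts",
    "fisher_p",
    "coassoc_score",
    "gene_categories",
    "coassociation_matrix",
    "SCORE_SIGNIFICANCE",
]

SCORE_SIGNIFICANCE = 2.0


@dataclass(frozen=True)
class OverlapCounts:
    """k of n group genes fall in an m-gene category, out of N eligible."""

    k: int
    n: int
    m: int
    N: int

    def __post_init__(self) -> None:
        if min(self.k, self.n, self.m, self.N) < 0:
            raise ValueError("counts must be non-negative")
        if self.k > min(self.n, self.m):
            raise ValueError("k cannot exceed min(n, m)")
        if max(self.n, self.m) > self.N:
            raise ValueError("n and m cannot exceed N")
        if self.N - self.n - self.m + self.k < 0:
            raise ValueError("implied fourth cell is negative")

    @property
    def expected(self) -> float:
        return self.n * self.m / self.N if self.N else 0.0


def fisher_p(counts: OverlapCounts, alternative: str = "two-sided") -> float:
    """Fisher exact p for the 2x2 overlap table; two-sided by default."""
    table = [
        [counts.k, counts.n - counts.k],
        [counts.m - counts.k, counts.N - counts.n - counts.m + counts.k],
    ]
    _, p = stats.fisher_exact(table, alternative=alternative)
    return float(min(max(p, 0.0), 1.0))


def coassoc_score(counts: OverlapCounts, p: float | None = None) -> float:
    """Signed score: -log10 p when the overlap exceeds expectation,
    +log10 p otherwise (so depletion scores are <= 0)."""
    if p is None:
        p = fisher_p(counts)
    mag = -np.log10(max(p, np.finfo(float).tiny))
    return float(mag if counts.k > counts.expected else -mag)


DEFAULT_CATEGORIES = ["pe", "sox2_pe", "nonsox2_pe", "pp", "sox2_promoter"]


def gene_categories(connectivity: pd.DataFrame) -> pd.DataFrame:
    """Boolean category membership per gene from a connectivity table.

    ``nonsox2_pe`` is exclusive: genes with promoter-enhancer
    interactions none of which involve a SOX2-bound enhancer anchor —
    the natural contrast to ``sox2_pe``.
    """
    pe = (connectivity["n_enhancer_partners"] > 0).to_numpy()
    sox = connectivity["has_sox2_pe"].to_numpy(dtype=bool)
    out = pd.DataFrame(
        {
            "gene_id": connectivity["gene_id"].to_numpy(),
            "pe": pe,
            "sox2_pe": pe & sox,
            "nonsox2_pe": pe & ~sox,
            "pp": (connectivity["n_promoter_partners"] > 0).to_numpy(),
        }
    )
    if "sox2_promoter" in connectivity.columns:
        out["sox2_promoter"] = connectivity["sox2_promoter"].to_numpy(dtype=bool)
    return out


def coassociation_matrix(
    groups: pd.Series,
    categories: pd.DataFrame,
    eligible: pd.Index | np.ndarray | list,
    alternative: str = "two-sided",
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """One signed-score cell per (expression group x interaction category).

    ``groups`` maps gene_id -> group label for eligible genes;
    ``categories`` is the boolean frame from :func:`gene_categories`.
    N = |eligible|, n = group size, m = category size, k = overlap, all
    restricted to eligible genes.
    """
    eligible = pd.Index(eligible).unique()
    if len(eligible) == 0:
        raise ValueError("eligible gene set is empty")
    groups = groups.reindex(eligible)
    cat = categories.set_index("gene_id").reindex(eligible).fillna(False)
    cat_cols = [c for c in cat.columns]
    N = len(eligible)
    rows = []
    order = group_order or sorted(x for x in groups.dropna().unique())
    for group in order:
        in_group = groups == group
        n = int(in_group.sum())
        for col in cat_cols:
            in_cat = cat[col].to_numpy(dtype=bool)
            m = int(in_cat.sum())
            k = int((in_group.to_numpy() & in_cat).sum())
            counts = OverlapCounts(k=k, n=n, m=m, N=N)
            p = fisher_p(counts, alternative=alternative)
            score = coassoc_score(counts, p)
            rows.append(
                {
                    "group": group,
                    "category": col,
                    "k": k, "n": n, "m": m, "N": N,
                    "expected": counts.expected,
                    "p": p,
                    "score": score,
                    "significant": abs(score) > SCORE_SIGNIFICANCE,
                }
            )
    return pd.DataFrame(rows)
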