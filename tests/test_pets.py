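"""PET engine: classification, dedup, clustering, and the significance
model, checked against exact-arithmetic and brute-force oracles."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import looplink as ll
from looplink import pets as lp


def make_pets(rows):
    """rows: (chrom_a, pos_a, chrom_b, pos_b) tuples."""
    df = pd.DataFrame(rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b"])
    df["strand_a"] = "+"
    df["strand_b"] = "+"
    df["linker_a"] = None
    df["linker_b"] = None
    return df[["chrom_a", "pos_a", "strand_a", "chrom_b", "pos_b", "strand_b",
               "linker_a", "linker_b"]]


class TestClassify:
    @pytest.mark.parametrize(
        "a,b,expect",
        [("A", "A", "non_chimeric"), ("B", "B", "non_chimeric"),
         ("A", "B", "chimeric"), ("B", "A", "chimeric"),
         (None, None, "non_chimeric")],
    )
    def test_linker_codes(self, a, b, expect):
        assert lp.classify_linker(a, b) == expect

    def test_unknown_linker_rejected(self):
        with pytest.raises(ValueError):
            lp.classify_linker("A", "X")

    @pytest.mark.parametrize(
        "pos_b,expect",
        [(8_000, "self_ligation"),   # boundary <= 8 kb inclusive
         (8_001, "intra_chromosomal")],
    )
    def test_self_span_boundary(self, pos_b, expect):
        pets = make_pets([("chr1", 0, "chr1", pos_b)])
        assert lp.classify_pets(pets).iloc[0] == expect
        assert lp.classify_pet(pets.iloc[0]) == expect

    def test_inter_chromosomal(self):
        pets = make_pets([("chr1", 100, "chr2", 100)])
        assert lp.classify_pets(pets).iloc[0] == "inter_chromosomal"

    def test_chimeric_wins(self):
        pets = make_pets([("chr1", 0, "chr1", 100_000)])
        pets.loc[0, "linker_a"] = "A"
        pets.loc[0, "linker_b"] = "B"
        assert lp.classify_pets(pets).iloc[0] == "chimeric"

    def test_class_counts_partition_input(self, planted_pets):
        cls = lp.classify_pets(planted_pets)
        assert cls.value_counts().sum() == len(planted_pets)
        assert set(cls.unique()) <= {
            "chimeric", "self_ligation", "intra_chromosomal", "inter_chromosomal"
        }


class TestDeduplicate:
    def test_exact_duplicate(self):
        pets = make_pets([("chr1", 100, "chr1", 50_000)] * 2)
        assert len(lp.deduplicate(pets)) == 1

    def test_joint_tolerance(self):
        both_within = make_pets(
            [("chr1", 100, "chr1", 50_000), ("chr1", 102, "chr1", 50_002)]
        )
        one_outside = make_pets(
            [("chr1", 100, "chr1", 50_000), ("chr1", 103, "chr1", 50_000)]
        )
        assert len(lp.deduplicate(both_within, tolerance=2)) == 1
        assert len(lp.deduplicate(one_outside, tolerance=2)) == 2

    def test_empty(self):
        pets = make_pets([])
        assert len(lp.deduplicate(pets)) == 0

    def test_order_invariant_and_conserving(self):
        rng = np.random.default_rng(5)
        base = [("chr1", int(p), "chr1", int(p) + 20_000)
                for p in rng.integers(0, 5_000, 60)]
        pets = make_pets(base)
        kept = lp.deduplicate(pets)
        shuffled = pets.iloc[rng.permutation(len(pets))].reset_index(drop=True)
        kept2 = lp.deduplicate(shuffled)
        key = ["chrom_a", "pos_a", "pos_b"]
        a = kept[key].sort_values(key).reset_index(drop=True)
        b = kept2[key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        assert len(kept) + (len(pets) - len(kept)) == len(pets)

    def test_retained_pets_pairwise_distinct(self):
        rng = np.random.default_rng(6)
        pets = make_pets(
            [("chr1", int(p), "chr1", int(q) + 20_000)
             for p, q in zip(rng.integers(0, 300, 80), rng.integers(0, 300, 80))]
        )
        kept = lp.deduplicate(pets, tolerance=2)
        pa = kept["pos_a"].to_numpy()
        pb = kept["pos_b"].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert abs(pa[i] - pa[j]) > 2 or abs(pb[i] - pb[j]) > 2


def brute_force_clusters(pa, pb, extension):
    """Transitive closure over all PET pairs (O(n^2) oracle)."""
    n = len(pa)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(pa[i] - pa[j]) <= extension and abs(pb[i] - pb[j]) <= extension:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(
        tuple(sorted((pa[i], pb[i]) for i in g))
        for g in groups.values()
        if len(g) >= 2
    )


class TestClusterIntraPets:
    def test_threshold_arithmetic_example(self):
        # left ends 100/900 chain (<=1 kb); 1901 splits (1001 > 1 kb)
        pets = make_pets(
            [("chr1", 100, "chr1", 50_000), ("chr1", 900, "chr1", 50_000),
             ("chr1", 1_901, "chr1", 50_000)]
        )
        out = lp.cluster_intra_pets(pets, extension=1_000)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["c"] == 2
        assert (row["a_start"], row["a_end"]) == (100, 901)
        assert (row["b_start"], row["b_end"]) == (50_000, 50_001)

    def test_identical_pets_single_cluster(self):
        pets = make_pets([("chr1", 1_000, "chr1", 90_000)] * 5)
        out = lp.cluster_intra_pets(pets)
        assert len(out) == 1
        assert out.iloc[0]["c"] == 5

    def test_matches_bruteforce_and_order_invariant(self):
        rng = np.random.default_rng(11)
        n = 200
        pa = rng.integers(0, 30_000, n)
        pb = pa + 20_000 + rng.integers(0, 30_000, n)
        pets = make_pets(
            [("chr1", int(a), "chr1", int(b)) for a, b in zip(pa, pb)]
        )
        expect = brute_force_clusters(pa.tolist(), pb.tolist(), 1_000)
        got = lp.cluster_intra_pets(pets, extension=1_000)
        assert len(got) == len(expect)
        expect_anchors = sorted(
            (min(a for a, _ in grp), max(a for a, _ in grp) + 1,
             min(b for _, b in grp), max(b for _, b in grp) + 1, len(grp))
            for grp in expect
        )
        got_anchors = sorted(
            (int(r["a_start"]), int(r["a_end"]), int(r["b_start"]),
             int(r["b_end"]), int(r["c"]))
            for _, r in got.iterrows()
        )
        assert got_anchors == expect_anchors
        shuffled = pets.iloc[rng.permutation(n)].reset_index(drop=True)
        got2 = lp.cluster_intra_pets(shuffled, extension=1_000)
        pd.testing.assert_frame_equal(got, got2)

    def test_partition_of_nonsingletons(self, loop_result):
        clusters = loop_result["clusters"]
        assert int(clusters["c"].sum()) <= len(loop_result["intra_pets"])
        assert (clusters["c"] >= 2).all()

    def test_rejects_interchromosomal(self):
        pets = make_pets([("chr1", 0, "chr2", 100)])
        with pytest.raises(ValueError):
            lp.cluster_intra_pets(pets)


def hypergeom_oracle(c, n_a, n_b, T):
    """Exact rational upper tail P(X >= c)."""
    denom = math.comb(T, n_a)
    num = sum(
        math.comb(n_b, k) * math.comb(T - n_b, n_a - k)
        for k in range(c, min(n_a, n_b) + 1)
    )
    return Fraction(num, denom)


class TestHypergeomPvalue:
    def test_zero_count_gives_one(self):
        assert lp.hypergeom_pvalue(0, 10, 10, 100) == 1.0

    def test_degenerate_certainty(self):
        assert lp.hypergeom_pvalue(10, 10, 10, 10) == pytest.approx(1.0)

    def test_against_exact_tail_sum(self):
        expect = float(hypergeom_oracle(5, 10, 10, 100))
        assert lp.hypergeom_pvalue(5, 10, 10, 100) == pytest.approx(expect, rel=1e-12)

    def test_symmetry_in_anchor_counts(self):
        assert lp.hypergeom_pvalue(3, 7, 12, 50) == pytest.approx(
            lp.hypergeom_pvalue(3, 12, 7, 50), rel=1e-12
        )

    def test_small_grid_exhaustive(self):
        for T in (5, 9, 14):
            for n_a in range(T + 1):
                for n_b in range(T + 1):
                    for c in range(min(n_a, n_b) + 1):
                        got = lp.hypergeom_pvalue(c, n_a, n_b, T)
                        expect = float(hypergeom_oracle(c, n_a, n_b, T))
                        assert got == pytest.approx(expect, rel=1e-10, abs=1e-14)

    @pytest.mark.parametrize("args", [(5, 3, 10, 100), (2, 200, 10, 100), (-1, 5, 5, 50)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            lp.hypergeom_pvalue(*args)


class TestBhFdr:
    def test_hand_computed_stepup(self):
        assert np.allclose(lp.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal_and_single(self):
        assert np.allclose(lp.bh_fdr([0.3, 0.3, 0.3]), 0.3)
        assert lp.bh_fdr([0.123])[0] == pytest.approx(0.123)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_dominates_p_and_preserves_order(self, pvals):
        q = lp.bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallSignificant:
    def _frame(self, c, p, q):
        return pd.DataFrame(
            {"chrom": ["chr1"], "a_start": [0], "a_end": [10],
             "b_start": [20_000], "b_end": [20_010],
             "c": [c], "p": [p], "q": [q]}
        )

    @pytest.mark.parametrize(
        "c,p,q,expect",
        [(3, 0.01, 0.04, True),    # iPET 3+, FDR < 0.05, p < 0.05
         (2, 0.01, 0.01, False),   # below in-situ iPET threshold
         (5, 0.01, 0.06, False),   # FDR fails
         (5, 0.06, 0.01, False)],  # raw p fails
    )
    def test_thresholds(self, c, p, q, expect):
        out = lp.call_significant(self._frame(c, p, q))
        assert bool(out["significant"].iloc[0]) is expect

    def test_tr1_dialect_allows_ipet2(self):
        out = lp.call_significant(
            self._frame(2, 0.01, 0.01), lp.ClusterParams.for_dialect("tr1")
        )
        assert bool(out["significant"].iloc[0])


class TestLoopsPerMillion:
    @pytest.mark.parametrize(
        "loops,intra,expect",
        [(7_046, 691_000, 10_197),
         (96_295, 13_105_813, 7_348),
         (0, 1_000_000, 0)],
    )
    def test_normalization(self, loops, intra, expect):
        assert lp.loops_per_million(loops, intra) == expect

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            lp.loops_per_million(10, 0)


class TestPipelineConservation:
    def test_counts_partition(self, loop_result, planted_pets):
        r = loop_result
        assert r["n_chimeric"] + r["n_non_chimeric"] == r["n_total"] == len(planted_pets)
        assert r["n_self"] + r["n_intra"] + r["n_inter"] == r["n_unique"]

    def test_cluster_stats_bounds(self, loop_result):
        cl = loop_result["clusters"]
        assert (cl["c"] <= np.minimum(cl["n_a"], cl["n_b"])).all()
        assert cl["p"].between(0, 1).all()
        assert (cl["q"] >= cl["p"] - 1e-12).all()


class TestShuffleNoise:
    def test_planted_signal_dwarfs_noise(self, loop_result):
        ratio = lp.shuffle_noise(loop_result["intra_pets"], n_iterations=5, seed=7)
        assert ratio < 0.1

    def test_requires_real_clusters(self):
        pets = make_pets([("chr1", 0, "chr1", 50_000), ("chr1", 9_000, "chr1", 90_000)])
        with pytest.raises(ValueError):
            lp.shuffle_noise(pets, n_iterations=2, seed=1)

    def test_deterministic_given_seed(self, loop_result):
        a = lp.shuffle_noise(loop_result["intra_pets"], n_iterations=3, seed=9)
        b = lp.shuffle_noise(loop_result["intra_pets"], n_iterations=3, seed=9)
        assert a == b
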