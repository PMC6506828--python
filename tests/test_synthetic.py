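"""Ground-truth generator: determinism, planted proportions, effect sizes,
and file round-trips."""
import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

import looplink as ll
from looplink import io as llio
from looplink.intervals import ChromIntervals


class TestMakeGenome:
    def test_counts_echo_inputs(self):
        g = ll.make_genome(1, n_chroms=2, chrom_length=5_000_000, n_genes=200)
        assert len(g.genes) == 200
        assert g.chrom_names == ["chr1", "chr2"]
        assert all(v == 5_000_000 for v in g.chrom_lengths.values())

    def test_deterministic(self):
        a = ll.make_genome(1, n_genes=100)
        b = ll.make_genome(1, n_genes=100)
        assert_frame_equal(a.genes, b.genes)
        assert not a.genes.equals(ll.make_genome(2, n_genes=100).genes)

    def test_genes_nonoverlapping_with_tss(self):
        g = ll.make_genome(3, n_genes=150)
        for _, sub in g.genes.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
        on_plus = g.genes["strand"] == "+"
        assert (g.genes.loc[on_plus, "tss"] == g.genes.loc[on_plus, "start"]).all()
        assert (g.genes.loc[~on_plus, "tss"] == g.genes.loc[~on_plus, "end"] - 1).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_chroms": 1},
            {"n_genes": 5},
            {"chrom_length": 500_000},
            {"n_genes": 5_000, "chrom_length": 1_000_000},  # cannot fit
        ],
    )
    def test_preconditions(self, kwargs):
        with pytest.raises(ValueError):
            ll.make_genome(1, **{"n_chroms": 2, "chrom_length": 5_000_000,
                                 "n_genes": 50, **kwargs})


class TestMakeArchitecture:
    def test_type_counts_within_binomial_band(self, std_genome):
        arch = ll.make_architecture(
            std_genome, 7, n_loops=1_000,
            frac_promoter_mediated=0.875, frac_pp_within_promoter_mediated=0.5,
        )
        counts = arch.loops["type_label"].value_counts()
        # expected ~437.5 P-P, ~437.5 P-nonP, ~125 nonP-nonP; check each
        # realized count inside the exact binomial 99% interval
        for label, p in [("P-P", 0.4375), ("P-nonP", 0.4375), ("nonP-nonP", 0.125)]:
            lo, hi = stats.binom.ppf([0.005, 0.995], 1_000, p)
            assert lo <= counts[label] <= hi, label

    def test_all_pp_boundary(self, std_genome):
        arch = ll.make_architecture(
            std_genome, 8, n_loops=50,
            frac_promoter_mediated=1.0, frac_pp_within_promoter_mediated=1.0,
        )
        assert set(arch.loops["type_label"]) == {"P-P"}

    def test_no_sox2_boundary(self, std_genome):
        arch = ll.make_architecture(std_genome, 9, n_loops=50, frac_distal_sox2=0.0)
        assert not arch.enhancers["sox2_bound"].any()

    def test_sox2_distal_anchors_mostly_active(self, std_genome):
        arch = ll.make_architecture(std_genome, 10, n_loops=1_000)
        sox = arch.enhancers[arch.enhancers["sox2_bound"]]
        assert len(sox) > 100
        assert (sox["mark_state"] == "active").mean() >= 0.95 - 0.03

    def test_sox2_peaks_inside_one_element(self, std_genome):
        """Every distal SOX2 peak lies inside exactly one enhancer."""
        arch = ll.make_architecture(std_genome, 11, n_loops=200)
        enh = arch.enhancers
        distal = arch.sox2_peaks[arch.sox2_peaks["name"].str.startswith("sox2_e")]
        for _, pk in distal.iterrows():
            inside = (
                (enh["chrom"] == pk["chrom"])
                & (enh["start"] <= pk["start"])
                & (enh["end"] >= pk["end"])
            )
            assert inside.sum() == 1

    def test_invalid_fraction_rejected(self, std_genome):
        with pytest.raises(ValueError):
            ll.make_architecture(std_genome, 1, n_loops=50, frac_promoter_mediated=1.2)
        with pytest.raises(ValueError):
            ll.make_architecture(std_genome, 1, n_loops=10)


class TestSimulatePets:
    def test_single_loop_signal_only(self, std_genome):
        arch = ll.make_architecture(std_genome, 12, n_loops=20,
                                    frac_promoter_mediated=1.0,
                                    frac_pp_within_promoter_mediated=1.0)
        one = arch.loops.iloc[[0]].reset_index(drop=True)
        arch_one = ll.PlantedArchitecture(
            arch.chrom_lengths, one, arch.enhancers, arch.sox2_peaks,
            arch.polII_peaks, arch.k27_regions, arch.k4me1_regions,
            arch.gene_enhancers, arch.truth_params,
        )
        pets = ll.simulate_pets(arch_one, 1, n_signal_pets=50)
        assert len(pets) == 50
        L = one.iloc[0]
        assert (pets["chrom_a"] == L["chrom"]).all()
        assert pets["pos_a"].between(L["a_start"], L["a_end"] - 1).all()
        assert pets["pos_b"].between(L["b_start"], L["b_end"] - 1).all()
        assert (ll.classify_pets(pets) == "intra_chromosomal").all()

    def test_all_chimeric_boundary(self, planted_arch):
        pets = ll.simulate_pets(planted_arch, 2, n_background_pets=500, chimera_rate=1.0)
        assert (ll.classify_pets(pets) == "chimeric").all()

    def test_pure_self_background_yields_no_clusters(self, planted_arch):
        pets = ll.simulate_pets(planted_arch, 3, n_signal_pets=0,
                                n_background_pets=2_000, background_mix=(1, 0, 0))
        cls = ll.classify_pets(pets)
        assert (cls == "self_ligation").all()
        intra = pets[cls == "intra_chromosomal"]
        assert len(ll.cluster_intra_pets(intra)) == 0

    def test_duplicates_collapse_back(self, planted_arch):
        clean = ll.simulate_pets(planted_arch, 4, n_background_pets=1_000,
                                 duplicate_rate=0.0)
        dup = ll.simulate_pets(planted_arch, 4, n_background_pets=1_000,
                               duplicate_rate=0.2)
        n_dup = len(dup) - len(clean)
        assert n_dup > 0
        retained = ll.deduplicate(dup)
        # greedy merging is deliberately non-transitive, so a duplicate
        # offset away from its group representative can survive; the vast
        # majority must still collapse
        survivors = len(retained) - len(ll.deduplicate(clean))
        assert survivors <= 0.1 * n_dup

    def test_mix_must_sum_to_one(self, planted_arch):
        with pytest.raises(ValueError):
            ll.simulate_pets(planted_arch, 1, n_background_pets=10,
                             background_mix=(0.5, 0.2, 0.2))


class TestSimulateExpression:
    def test_identity_when_no_downregulation(self, std_genome, planted_arch):
        model = ll.EffectModel(mut_downregulation_factor=1.0,
                               background_down_fraction=0.0, seed=5)
        expr = ll.simulate_expression(planted_arch, std_genome, model)
        assert np.allclose(expr["true_wt_mean"], expr["true_mut_mean"])
        assert not expr["planted_down"].any()

    def test_enhancer_boost_ratio(self, std_genome, planted_arch):
        """3 connected enhancers vs 0 at boost 1.5 -> mean ratio 1.5^3."""
        model = ll.EffectModel(base_log_tpm_sigma=0.0, per_enhancer_boost=1.5, seed=6)
        expr = ll.simulate_expression(planted_arch, std_genome, model)
        base = expr.loc[expr["n_enhancers"] == 0, "true_wt_mean"].iloc[0]
        synthetic_three = base * 1.5**3
        assert np.isclose(synthetic_three / base, 3.375)
        one = expr.loc[expr["n_enhancers"] == 1, "true_wt_mean"]
        assert np.allclose(one / base, 1.5)

    def test_planted_log2_fold(self, std_genome, planted_arch):
        model = ll.EffectModel(mut_downregulation_factor=0.15, seed=7)
        expr = ll.simulate_expression(planted_arch, std_genome, model)
        planted = expr[expr["planted_down"]]
        assert len(planted) > 0
        lfc = np.log2(planted["true_wt_mean"] / planted["true_mut_mean"])
        assert np.allclose(lfc, -np.log2(0.15))
        assert np.isclose(lfc.iloc[0], 2.7369656, atol=1e-6)

    def test_replicate_noise_cv_converges(self, std_genome, planted_arch):
        model = ll.EffectModel(replicate_noise_cv=0.2, n_replicates=200, seed=8)
        expr = ll.simulate_expression(planted_arch, std_genome, model)
        wt_cols = [c for c in expr.columns if c.startswith("tpm_wt_")]
        emp = expr[wt_cols].std(axis=1) / expr[wt_cols].mean(axis=1)
        assert abs(emp.mean() - 0.2) < 0.02

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ll.EffectModel(mut_downregulation_factor=0.0)
        with pytest.raises(ValueError):
            ll.EffectModel(mut_downregulation_factor=1.5)


@pytest.fixture(scope="module")
def dataset():
    return ll.make_dataset(
        42,
        genome_kwargs={"n_chroms": 2, "chrom_length": 2_000_000, "n_genes": 40},
        arch_kwargs={"n_loops": 25},
        pet_kwargs={"n_background_pets": 500, "duplicate_rate": 0.05,
                    "chimera_rate": 0.05},
    )


class TestDatasetRoundTrip:

    def test_deterministic_dataset(self, dataset):
        again = ll.make_dataset(
            42,
            genome_kwargs={"n_chroms": 2, "chrom_length": 2_000_000, "n_genes": 40},
            arch_kwargs={"n_loops": 25},
            pet_kwargs={"n_background_pets": 500, "duplicate_rate": 0.05,
                        "chimera_rate": 0.05},
        )
        assert_frame_equal(dataset.pets, again.pets)
        assert_frame_equal(dataset.expression, again.expression)
        assert_frame_equal(dataset.arch.loops, again.arch.loops)

    def test_round_trip(self, dataset, tmp_path):
        ll.write_dataset(dataset, tmp_path / "d")
        back = ll.read_dataset(tmp_path / "d")
        assert_frame_equal(back.pets, dataset.pets)
        assert_frame_equal(back.genome.genes, dataset.genome.genes,
                           check_dtype=False)
        assert_frame_equal(back.arch.loops, dataset.arch.loops, check_dtype=False)
        tpm = [c for c in dataset.expression.columns if c.startswith("tpm_")]
        assert np.allclose(back.expression[tpm], dataset.expression[tpm])
        for key, track in dataset.bins["tracks"].items():
            for chrom, arr in track.items():
                assert np.array_equal(back.bins["tracks"][key][chrom], arr)

    def test_truth_contains_seed(self, dataset, tmp_path):
        ll.write_dataset(dataset, tmp_path / "d2")
        truth = llio.read_json(tmp_path / "d2" / "truth.json")
        assert truth["params"]["seed"] == 42

    def test_written_bed_respects_bounds(self, dataset, tmp_path):
        ll.write_dataset(dataset, tmp_path / "d3")
        for name in ("sox2_peaks.bed", "polII_peaks.bed",
                     "h3k27ac_peaks.bed", "h3k4me1_peaks.bed"):
            bed = llio.read_bed(tmp_path / "d3" / name)
            lengths = bed["chrom"].map(dataset.arch.chrom_lengths)
            assert (bed["start"] >= 0).all()
            assert (bed["start"] < bed["end"]).all()
            assert (bed["end"] <= lengths).all()

    def test_byte_identical_writes(self, dataset, tmp_path):
        ll.write_dataset(dataset, tmp_path / "w1")
        ll.write_dataset(dataset, tmp_path / "w2")
        for f in sorted((tmp_path / "w1").iterdir()):
            assert f.read_bytes() == (tmp_path / "w2" / f.name).read_bytes()


def test_planted_loops_geometrically_consistent(planted_arch, std_genome):
    """Promoter anchors overlap a TSS window; distal anchors never do."""
    prom = ChromIntervals.from_frame(std_genome.promoter_windows(2_500))
    loops = planted_arch.loops
    for side in ("a", "b"):
        hits = prom.overlaps_frame(
            loops.rename(columns={f"{side}_start": "start", f"{side}_end": "end"})
        )
        assert np.array_equal(hits, loops[f"gene_{side}"].notna().to_numpy())
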