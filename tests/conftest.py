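import numpy as np
import pandas as pd
import pytest

import looplink as ll


@pytest.fixture(scope="session")
def std_genome():
    """Four 25-Mb chromosomes, 2000 genes: the standard study genome."""
    return ll.make_genome(101, n_chroms=4, chrom_length=25_000_000, n_genes=2_000)


@pytest.fixture(scope="session")
def planted_arch(std_genome):
    """50 planted loops at intensity 10 (>=8 iPETs nominal)."""
    return ll.make_architecture(std_genome, 102, n_loops=50, loop_intensity=10.0)


@pytest.fixture(scope="session")
def planted_pets(planted_arch):
    """Planted signal over ~10x power-law background."""
    return ll.simulate_pets(planted_arch, 103, n_background_pets=5_000)


@pytest.fixture(scope="session")
def loop_result(planted_pets):
    return ll.call_loops(planted_pets)


@pytest.fixture(scope="session")
def regulatory_dataset(std_genome):
    """Architecture + expression at the study effect sizes (MUT factor
    0.15 on SOX2-enhancer-connected genes, CV 0.2, 3 replicates)."""
    arch = ll.make_architecture(std_genome, 502, n_loops=400)
    model = ll.EffectModel(seed=503)
    expr = ll.simulate_expression(arch, std_genome, model)
    return arch, model, expr


@pytest.fixture(scope="session")
def truth_connectivity(std_genome, regulatory_dataset):
    """Ground-truth per-gene connectivity from the planted architecture."""
    arch, _, _ = regulatory_dataset
    conn = arch.gene_enhancers.groupby("gene_id").agg(
        n_enhancer_partners=("enh_id", "size"), has_sox2_pe=("sox2_bound", "any")
    )
    genes = std_genome.genes["gene_id"]
    pp = set()
    for _, row in arch.loops[arch.loops["type_label"] == "P-P"].iterrows():
        pp.add(row["gene_a"])
        pp.add(row["gene_b"])
    out = pd.DataFrame({"gene_id": genes})
    out = out.merge(conn, on="gene_id", how="left")
    out["n_enhancer_partners"] = out["n_enhancer_partners"].fillna(0).astype(int)
    out["has_sox2_pe"] = out["has_sox2_pe"].eq(True)
    out["n_promoter_partners"] = out["gene_id"].isin(pp).astype(int)
    out["category"] = np.where(
        out["n_enhancer_partners"] > 0, "has_pe",
        np.where(out["n_promoter_partners"] > 0, "pp_only", "not_connected"),
    )
    return out


def match_loops(called: pd.DataFrame, planted: pd.DataFrame, tol: int = 1_000):
    """(n_recovered, n_false_positive) by anchor-midpoint matching."""
    def mids(df, sa, ea, sb, eb):
        return ((df[sa] + df[ea]) // 2).to_numpy(), ((df[sb] + df[eb]) // 2).to_numpy()

    rec = 0
    for _, L in planted.iterrows():
        am, bm = (L["a_start"] + L["a_end"]) // 2, (L["b_start"] + L["b_end"]) // 2
        s = called[called["chrom"] == L["chrom"]]
        sa, sb = mids(s, "a_start", "a_end", "b_start", "b_end")
        if ((np.abs(sa - am) <= tol) & (np.abs(sb - bm) <= tol)).any():
            rec += 1
    fp = 0
    for _, s in called.iterrows():
        sa = (s["a_start"] + s["a_end"]) // 2
        sb = (s["b_start"] + s["b_end"]) // 2
        L = planted[planted["chrom"] == s["chrom"]]
        am, bm = mids(L, "a_start", "a_end", "b_start", "b_end")
        if not ((np.abs(am - sa) <= tol) & (np.abs(bm - sb) <= tol)).any():
            fp += 1
    return rec, fp
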