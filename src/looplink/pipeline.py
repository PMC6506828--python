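"""End-to-end pipeline: simulate -> call loops -> annotate -> enrich ->
express -> co-associate -> report.

A single :class:`PipelineConfig` carries every threshold; one global seed
is fanned out to per-stage seeds by a fixed derivation so any stage can
be re-run in isolation and reproduce its persisted outputs. All stage
artifacts are plain text (TSV/BED/BEDPE/bedGraph/JSON).
"""
from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchors as ll_anchors
from . import coassoc as ll_coassoc
from . import expression as ll_expr
from . import io as llio
from . import marks as ll_marks
from . import pets as ll_pets
from . import synthetic as ll_syn
from .genome import Genome
from .intervals import ChromIntervals

log = logging.getLogger("looplink")

__all__ = ["PipelineConfig", "derive_seed", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, serialisable to JSON."""

    seed: int = 1
    dialect: str = "insitu"          # tr1 | insitu
    self_span: int = 8_000
    extension: int = 1_000
    dedup_tolerance: int = 2
    fdr_cutoff: float = 0.05
    p_cutoff: float = 0.05
    promoter_window: int = 2_500     # anchor annotation
    mark_promoter_window: int = 1_000  # histone-mark promoter split
    mark_min_len: int = 2_000
    bin_size: int = 200
    binarize_p: float = 1e-4
    chi2_threshold: float = 1e-4
    tpm_floor_distributions: float = 0.0
    tpm_floor_fold: float = 1.0
    tpm_floor_grouping: float = 5.0
    fold_threshold: float = 1.5
    q_significant: float = 0.05
    q_moderate: float = 0.2
    n_random_sets: int = 1_000
    n_permutations: int = 1_000
    noise_iterations: int = 20
    # synthetic-dataset condition parameters
    n_chroms: int = 4
    chrom_length: int = 25_000_000
    n_genes: int = 2_000
    n_loops: int = 400
    n_background_pets: int = 5_000
    frac_promoter_mediated: float = 0.875
    frac_pp_within_promoter_mediated: float = 0.5
    frac_distal_sox2: float = 0.385
    loop_intensity: float = 8.0
    mut_downregulation_factor: float = 0.15

    @property
    def cluster_params(self) -> ll_pets.ClusterParams:
        base = ll_pets.ClusterParams.for_dialect(self.dialect)
        return ll_pets.ClusterParams(
            self_span=self.self_span,
            extension=self.extension,
            dedup_tolerance=self.dedup_tolerance,
            min_ipet=base.min_ipet,
            fdr_cutoff=self.fdr_cutoff,
            p_cutoff=self.p_cutoff,
        )

    def to_json(self, path) -> None:
        llio.write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**llio.read_json(path))


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


def stage_simulate(config: PipelineConfig, outdir: Path) -> ll_syn.SyntheticDataset:
    ds = ll_syn.make_dataset(
        derive_seed(config.seed, "simulate"),
        genome_kwargs={
            "n_chroms": config.n_chroms,
            "chrom_length": config.chrom_length,
            "n_genes": config.n_genes,
        },
        arch_kwargs={
            "n_loops": config.n_loops,
            "frac_promoter_mediated": config.frac_promoter_mediated,
            "frac_pp_within_promoter_mediated": config.frac_pp_within_promoter_mediated,
            "frac_distal_sox2": config.frac_distal_sox2,
            "loop_intensity": config.loop_intensity,
        },
        pet_kwargs={"n_background_pets": config.n_background_pets},
        effect_kwargs={"mut_downregulation_factor": config.mut_downregulation_factor},
        bin_kwargs={"bin_size": config.bin_size},
    )
    ll_syn.write_dataset(ds, outdir / "data")
    log.info("simulate: %d PETs, %d genes, %d planted loops",
             len(ds.pets), len(ds.genome.genes), len(ds.arch.loops))
    return ds


def stage_call_loops(config: PipelineConfig, outdir: Path) -> dict:
    pets = llio.read_tagpairs(outdir / "data" / "pets.tsv")
    res = ll_pets.call_loops(pets, config.cluster_params)
    cl = res["clusters"]
    bedpe = pd.DataFrame(
        {
            "chrom_a": cl["chrom"], "start_a": cl["a_start"], "end_a": cl["a_end"],
            "chrom_b": cl["chrom"], "start_b": cl["b_start"], "end_b": cl["b_end"],
            "c": cl["c"], "n_a": cl["n_a"], "n_b": cl["n_b"],
            "p": cl["p"], "q": cl["q"], "significant": cl["significant"],
        }
    )
    llio.write_bedpe(bedpe, outdir / "clusters.bedpe")
    counts = {k: v for k, v in res.items() if isinstance(v, int)}
    counts["n_significant"] = int(res["clusters"]["significant"].sum())
    if counts["n_intra"] > 0:
        counts["loops_per_million"] = ll_pets.loops_per_million(
            counts["n_significant"], counts["n_intra"]
        )
    llio.write_json(counts, outdir / "loop_stats.json")
    llio.write_tagpairs(res["intra_pets"], outdir / "intra_pets.tsv")
    log.info("call-loops: %d clusters, %d significant",
             len(res["clusters"]), counts["n_significant"])
    return res


def _read_genome(outdir: Path) -> Genome:
    genes = llio.read_genes_tsv(outdir / "data" / "genes.tsv")
    truth = llio.read_json(outdir / "data" / "truth.json")
    return Genome({k: int(v) for k, v in truth["chrom_lengths"].items()}, genes)


def stage_annotate(config: PipelineConfig, outdir: Path) -> dict:
    genome = _read_genome(outdir)
    clusters = llio.read_bedpe(outdir / "clusters.bedpe")
    clusters = clusters.rename(
        columns={"chrom_a": "chrom", "start_a": "a_start", "end_a": "a_end",
                 "start_b": "b_start", "end_b": "b_end"}
    )
    sig = clusters[clusters["significant"].astype(bool)].reset_index(drop=True)
    sox2 = llio.read_bed(outdir / "data" / "sox2_peaks.bed")
    polII = llio.read_bed(outdir / "data" / "polII_peaks.bed")
    annotated = ll_anchors.annotate_interactions(
        sig, genome, sox2, polII, config.promoter_window
    )
    anchor_frames = pd.concat(
        [
            annotated[["chrom", "a_start", "a_end"]].rename(
                columns={"a_start": "start", "a_end": "end"}),
            annotated[["chrom", "b_start", "b_end"]].rename(
                columns={"b_start": "start", "b_end": "end"}),
        ],
        ignore_index=True,
    )
    nodes = ll_anchors.build_nodes(anchor_frames, genome, config.promoter_window)
    conn = ll_anchors.summarize_connectivity(
        annotated, genome, sox2, config.promoter_window
    )
    annotated.to_csv(outdir / "interactions_annotated.tsv", sep="\t", index=False)
    llio.write_bed(
        nodes.assign(name=[f"node{i+1}" for i in range(len(nodes))]),
        outdir / "nodes.bed", extra_cols=["is_promoter"],
    )
    conn.to_csv(outdir / "connectivity.tsv", sep="\t", index=False)
    log.info("annotate: %d significant interactions, %d nodes", len(annotated), len(nodes))
    return {"annotated": annotated, "nodes": nodes, "connectivity": conn, "genome": genome}


def _coverage_windows(track: dict[str, np.ndarray], bin_size: int,
                      chrom_lengths: dict[str, int],
                      window: int = 3_000, step: int = 500) -> dict[str, np.ndarray]:
    """Sliding-window read counts from per-bin counts (for the mask)."""
    out = {}
    for chrom, counts in track.items():
        length = chrom_lengths[chrom]
        pos_counts = np.zeros(length // step + 1, dtype=np.int64)
        # distribute each bin's count onto its containing step-slot
        slots = (np.arange(len(counts)) * bin_size) // step
        np.add.at(pos_counts, slots, counts)
        n_win = max((length - window) // step + 1, 1)
        win_slots = window // step
        c = np.concatenate([[0], np.cumsum(pos_counts)])
        out[chrom] = np.array(
            [c[min(i + win_slots, len(c) - 1)] - c[i] for i in range(n_win)],
            dtype=np.int64,
        )
    return out


def stage_enrich(config: PipelineConfig, outdir: Path) -> dict:
    genome = _read_genome(outdir)
    truth = llio.read_json(outdir / "data" / "truth.json")
    bin_size = int(truth["bin_size"])
    sox2 = llio.read_bed(outdir / "data" / "sox2_peaks.bed")
    k27 = llio.read_bed(outdir / "data" / "h3k27ac_peaks.bed")

    # pooled coverage across marks/conditions defines mappability
    tracks = {}
    for mark in ("H3K27ac", "H3K4me1"):
        for cond in ("wt", "mut"):
            path = outdir / "data" / f"bins_{mark}_{cond}.bedGraph"
            t = llio.read_bedgraph(path, bin_size)
            for chrom, arr in t.items():
                if chrom in tracks:
                    n = max(len(tracks[chrom]), len(arr))
                    merged = np.zeros(n, dtype=np.int64)
                    merged[: len(tracks[chrom])] += tracks[chrom]
                    merged[: len(arr)] += arr
                    tracks[chrom] = merged
                else:
                    tracks[chrom] = arr.copy()
    windows = _coverage_windows(tracks, bin_size, genome.chrom_lengths)
    mask = ll_marks.build_unmappable_mask(windows, genome.chrom_lengths)

    std = ll_marks.standardize_peaks(k27, config.mark_min_len)
    _, distal = ll_marks.split_promoter_distal(
        std, genome.tss_by_chrom(), config.mark_promoter_window
    )
    result = ll_marks.empirical_enrichment(
        sox2, distal, mask, genome.chrom_lengths,
        n_sets=config.n_random_sets,
        seed=derive_seed(config.seed, "enrich"),
    )
    report = {
        "observed": result.observed,
        "null_mean": result.null_mean,
        "null_sd": result.null_sd,
        "empirical_p": result.empirical_p,
        "n_sets": config.n_random_sets,
        "masked_bp": mask.total_length(),
    }
    llio.write_json(report, outdir / "enrichment.json")
    log.info("enrich: observed=%d null_mean=%.1f p=%.4g",
             result.observed, result.null_mean, result.empirical_p)
    return report


def stage_express(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    expr = llio.read_expression(outdir / "data" / "expression.tsv")
    conn = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    records = ll_expr.summarize_expression(expr)
    pq = ll_expr.differential_qvalues(
        records,
        seed=derive_seed(config.seed, "express"),
        n_permutations=config.n_permutations,
    )
    records["p"] = pq["p"]
    records["q"] = pq["q"]
    records["fold_ratio"] = ll_expr.fold_ratio(
        records["mean_wt"], records["mean_mut"], config.tpm_floor_fold
    )
    records["group"] = ll_expr.assign_groups(
        records, config.tpm_floor_grouping, config.fold_threshold,
        config.q_significant, config.q_moderate,
    )
    summaries = ll_expr.expression_by_category(
        records, conn, config.tpm_floor_distributions
    )
    trend = ll_expr.expression_vs_enhancer_count(
        records, conn, config.tpm_floor_distributions
    )
    out_cols = ["gene_id", "mean_wt", "mean_mut", "p", "q", "fold_ratio", "group"]
    records[out_cols].to_csv(outdir / "genes_grouped.tsv", sep="\t", index=False)
    summaries.to_csv(outdir / "category_summaries.tsv", sep="\t", index=False)
    llio.write_json(
        {
            "spearman_rho": trend["spearman_rho"],
            "spearman_p": trend["spearman_p"],
            "medians_by_enhancer_count": trend["medians"].reset_index(),
        },
        outdir / "expression_stats.json",
    )
    log.info("express: %d genes, %d in group1",
             len(records), int((records["group"] == "group1").sum()))
    return records


def stage_coassoc(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    records = pd.read_csv(outdir / "genes_grouped.tsv", sep="\t")
    conn = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    eligible = records.loc[
        (records["mean_wt"] > config.tpm_floor_grouping)
        | (records["mean_mut"] > config.tpm_floor_grouping),
        "gene_id",
    ]
    groups = records.set_index("gene_id")["group"]
    cats = ll_coassoc.gene_categories(conn)
    matrix = ll_coassoc.coassociation_matrix(
        groups, cats, eligible, group_order=["group1", "group2", "group3"]
    )
    matrix.to_csv(outdir / "coassociation.tsv", sep="\t", index=False)
    log.info("coassoc: %d cells", len(matrix))
    return matrix


def stage_report(config: PipelineConfig, outdir: Path) -> dict:
    loop_stats = llio.read_json(outdir / "loop_stats.json")
    annotated = pd.read_csv(outdir / "interactions_annotated.tsv", sep="\t")
    nodes = llio.read_bed(outdir / "nodes.bed", extra_cols=["is_promoter"])
    matrix = pd.read_csv(outdir / "coassociation.tsv", sep="\t")
    type_counts = annotated["itype"].value_counts().to_dict()
    n_sig = len(annotated)
    summary = {
        "pets": loop_stats,
        "significant_interactions": n_sig,
        "polII_bound_interactions": int(annotated["polII_both"].sum()) if n_sig else 0,
        "interaction_type_counts": {k: int(v) for k, v in type_counts.items()},
        "interaction_type_fractions": {
            k: v / n_sig for k, v in type_counts.items()
        } if n_sig else {},
        "nodes_total": int(len(nodes)),
        "nodes_promoter": int(nodes["is_promoter"].astype(bool).sum()) if len(nodes) else 0,
        "coassociation": matrix,
        "config": asdict(config),
    }
    if loop_stats.get("n_intra"):
        summary["loops_per_million"] = ll_pets.loops_per_million(
            n_sig, loop_stats["n_intra"]
        )
        summary["polII_loops_per_million"] = ll_pets.loops_per_million(
            summary["polII_bound_interactions"], loop_stats["n_intra"]
        )
    llio.write_json(summary, outdir / "run_summary.json")
    return summary


STAGES = ["simulate", "call-loops", "annotate", "enrich", "express", "coassoc", "report"]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order; identical config + seed reproduce an
    identical run summary. A stage failure aborts with the stage named;
    earlier stages' outputs are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    steps = {
        "simulate": stage_simulate,
        "call-loops": stage_call_loops,
        "annotate": stage_annotate,
        "enrich": stage_enrich,
        "express": stage_express,
        "coassoc": stage_coassoc,
        "report": stage_report,
    }
    result = None
    for stage in STAGES:
        try:
            result = steps[stage](config, outdir)
        except Exception as err:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return result


def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Schema and coordinate sanity checks, with line numbers.

    ``paths`` maps kinds ('pets', 'genes', any '*_bed') to file paths.
    Returns a list of {file, line, level, message} issues; an empty list
    means the inputs look clean.
    """
    issues: list[dict] = []
    chrom_sets: dict[str, set] = {}

    def issue(path, line, level, message):
        issues.append({"file": str(path), "line": line, "level": level,
                       "message": message})

    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            issue(path, 0, "error", "file not found")
            continue
        if kind == "pets":
            try:
                df = llio.read_tagpairs(path)
            except Exception as err:
                issue(path, 0, "error", f"unreadable tag-pair TSV: {err}")
                continue
            bad = (df["pos_a"] < 0) | (df["pos_b"] < 0)
            for i in np.flatnonzero(bad.to_numpy()):
                issue(path, int(i) + 2, "error", "negative tag position")
            chrom_sets[kind] = set(df["chrom_a"]) | set(df["chrom_b"])
        elif kind == "genes":
            df = llio.read_genes_tsv(path)
            bad = df["start"] >= df["end"]
            for i in np.flatnonzero(bad.to_numpy()):
                issue(path, int(i) + 2, "error", "gene start >= end")
            chrom_sets[kind] = set(df["chrom"])
        elif kind.endswith("bed"):
            with open(path) as fh:
                chroms = set()
                for ln, raw in enumerate(fh, start=1):
                    fields = raw.rstrip("\n").split("\t")
                    if len(fields) < 3:
                        issue(path, ln, "error", "fewer than 3 BED columns")
                        continue
                    try:
                        s, e = int(fields[1]), int(fields[2])
                    except ValueError:
                        issue(path, ln, "error", "non-integer BED coordinates")
                        continue
                    if not 0 <= s < e:
                        issue(path, ln, "error",
                              f"invalid interval [{s}, {e})")
                    chroms.add(fields[0])
                chrom_sets[kind] = chroms
    if "genes" in chrom_sets:
        for kind, chroms in chrom_sets.items():
            if kind == "genes":
                continue
            extra = chroms - chrom_sets["genes"]
            if extra:
                issue(paths[kind], 0, "warning",
                      f"chromosomes absent from gene model: {sorted(extra)}")
    return issues
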