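"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: tag-pair TSV (one PET per row), BED6 peak sets, BED12 or TSV gene
models, BEDPE interaction clusters, bedGraph bin-count tracks, expression
TSV, and a truth/provenance JSON for synthetic datasets. All coordinates
are 0-based half-open, matching BED.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

TAGPAIR_COLUMNS = [
    "chrom_a", "pos_a", "strand_a",
    "chrom_b", "pos_b", "strand_b",
    "linker_a", "linker_b",
]

MISSING = "."


def write_tagpairs(df: pd.DataFrame, path) -> None:
    out = df[TAGPAIR_COLUMNS].copy()
    for col in ("linker_a", "linker_b"):
        out[col] = out[col].where(out[col].notna(), MISSING)
    out.to_csv(path, sep="\t", index=False)


def read_tagpairs(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom_a": str, "chrom_b": str, "pos_a": np.int64, "pos_b": np.int64},
        keep_default_na=False,
    )
    for col in ("linker_a", "linker_b"):
        df[col] = df[col].replace(MISSING, None)
        df[col] = df[col].where(pd.notna(df[col]), None)
    return df[TAGPAIR_COLUMNS]


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    """BED6 (+ optional extra columns appended after strand)."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "name": df["name"] if "name" in df.columns else MISSING,
            "score": df["score"] if "score" in df.columns else 0,
            "strand": df["strand"] if "strand" in df.columns else MISSING,
        }
    )
    for col in extra_cols or []:
        out[col] = df[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"] + list(extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#", keep_default_na=False)
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_genes_bed12(genes: pd.DataFrame, path) -> None:
    n = len(genes)
    size = (genes["end"] - genes["start"]).astype(np.int64)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": np.zeros(n, dtype=int),
            "strand": genes["strand"],
            "thick_start": genes["start"],
            "thick_end": genes["end"],
            "rgb": ["0"] * n,
            "block_count": np.ones(n, dtype=int),
            "block_sizes": [f"{s}," for s in size],
            "block_starts": ["0,"] * n,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed12(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(6),
                     names=["chrom", "start", "end", "gene_id", "score", "strand"],
                     dtype={0: str})
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["gene_id", "chrom", "start", "end", "strand", "tss"]]


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand", "tss"]].to_csv(
        path, sep="\t", index=False
    )


def read_genes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


BEDPE_COLUMNS = [
    "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
    "name", "c", "p", "q", "significant",
]


def write_bedpe(clusters: pd.DataFrame, path) -> None:
    df = clusters.copy()
    if "name" not in df.columns:
        df["name"] = [f"loop{i + 1}" for i in range(len(df))]
    for col in BEDPE_COLUMNS:
        if col not in df.columns:
            df[col] = MISSING
    extra = [c for c in clusters.columns if c not in BEDPE_COLUMNS]
    df[BEDPE_COLUMNS + extra].to_csv(path, sep="\t", index=False)


def read_bedpe(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})


def write_bedgraph(track: dict[str, np.ndarray], bin_size: int, path) -> None:
    """One row per bin; the last bin of a chromosome may be partial."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            counts = np.asarray(track[chrom])
            starts = np.arange(len(counts), dtype=np.int64) * bin_size
            for s, v in zip(starts, counts):
                fh.write(f"{chrom}\t{s}\t{s + bin_size}\t{int(v)}\n")


def read_bedgraph(path, bin_size: int) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], dtype={0: str})
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        idx = (sub["start"].to_numpy() // bin_size).astype(np.int64)
        arr = np.zeros(idx.max() + 1 if len(idx) else 0, dtype=np.int64)
        arr[idx] = sub["value"].to_numpy()
        out[str(chrom)] = arr
    return out


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
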