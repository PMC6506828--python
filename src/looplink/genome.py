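"""Genome and gene-model containers.

A :class:`Genome` is the minimal annotation the pipeline needs: chromosome
lengths and a gene table with one transcription start site (TSS) per gene.
Real annotations arrive through :mod:`looplink.io` readers (BED12 or TSV);
synthetic genomes are built by :func:`looplink.synthetic.make_genome`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


@dataclass
class Genome:
    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # columns GENE_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        g = self.genes
        for _, row in g.iterrows():
            if row["chrom"] not in self.chrom_lengths:
                raise ValueError(f"gene {row['gene_id']} on unknown chromosome {row['chrom']}")
        lengths = g["chrom"].map(self.chrom_lengths)
        if ((g["start"] < 0) | (g["end"] > lengths)).any():
            raise ValueError("gene body outside chromosome bounds")
        if g.duplicated(subset=["chrom", "tss"]).any():
            raise ValueError("TSS positions must be unique per gene")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def tss_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted TSS positions per chromosome."""
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self.genes.groupby("chrom", sort=True):
            out[str(chrom)] = np.sort(sub["tss"].to_numpy(dtype=np.int64))
        return out

    def promoter_windows(self, window: int = 2500) -> pd.DataFrame:
        """Promoter intervals [tss-window, tss+window+1), endpoint inclusive."""
        g = self.genes
        lengths = g["chrom"].map(self.chrom_lengths).to_numpy()
        return pd.DataFrame(
            {
                "gene_id": g["gene_id"].to_numpy(),
                "chrom": g["chrom"].to_numpy(),
                "start": np.maximum(g["tss"].to_numpy() - window, 0),
                "end": np.minimum(g["tss"].to_numpy() + window + 1, lengths),
                "tss": g["tss"].to_numpy(),
            }
        )
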