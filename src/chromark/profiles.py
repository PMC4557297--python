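"""Input-corrected enrichment profiles.

Two layouts: a 100-bin metagene matrix (25 flank bins of 200 bp on each
side plus 50 equal-width gene-body bins, genes shorter than 500 bp
excluded) and a 50-bin TSS matrix (200-bp bins spanning +/-5 kb).  Bins are
ordered 5'->3' in gene orientation; values are pseudo-counted ratios of
depth-scaled chip over input counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ChromSizes, GeneModel, GenomicInterval, TagLibrary

__all__ = [
    "ProfileMatrix",
    "METAGENE_100",
    "TSS_50",
    "bin_counts",
    "enrichment_ratio",
    "metagene_matrix",
    "tss_matrix",
    "total_tss_enrichment",
    "average_profile",
]

log = logging.getLogger(__name__)

METAGENE_100 = "METAGENE_100"
TSS_50 = "TSS_50"

FLANK_BINS = 25
BODY_BINS = 50
FLANK_BIN_BP = 200
TSS_BINS = 50
TSS_BIN_BP = 200
MIN_GENE_SPAN = 500


@dataclass
class ProfileMatrix:
    layout: str
    gene_ids: List[str]
    values: np.ndarray  # genes x bins
    clipped: np.ndarray  # per-gene flag: some bins hit a chromosome edge
    n_excluded: int = 0

    def __post_init__(self) -> None:
        expected = 100 if self.layout == METAGENE_100 else 50
        if self.values.shape != (len(self.gene_ids), expected):
            raise ValueError(
                f"{self.layout} matrix must be n_genes x {expected}, "
                f"got {self.values.shape}"
            )

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        if self.layout == METAGENE_100:
            cols = (
                [f"up_{i}" for i in range(FLANK_BINS)]
                + [f"body_{i}" for i in range(BODY_BINS)]
                + [f"down_{i}" for i in range(FLANK_BINS)]
            )
        else:
            cols = [f"tss_{(i - 25) * TSS_BIN_BP}" for i in range(TSS_BINS)]
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=cols)
        df.index.name = "gene_id"
        return df


def bin_counts(tags: TagLibrary, bins: Sequence[GenomicInterval]) -> np.ndarray:
    """Tag midpoints falling in each (possibly overlapping) bin."""
    out = np.zeros(len(bins), dtype=np.int64)
    for i, iv in enumerate(bins):
        pos = tags.positions.get(iv.chrom)
        if pos is None or len(pos) == 0:
            continue
        out[i] = np.searchsorted(pos, iv.end, side="left") - np.searchsorted(
            pos, iv.start, side="left"
        )
    return out


def enrichment_ratio(
    chip_count, input_count, scale: float, pseudo: float = 1.0
):
    """Pseudo-counted ratio of chip over depth-scaled input counts."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    chip_count = np.asarray(chip_count, dtype=float)
    input_count = np.asarray(input_count, dtype=float)
    return (chip_count + pseudo) / (input_count * scale + pseudo)


def _count_range(pos: Optional[np.ndarray], start: int, end: int) -> int:
    if pos is None or len(pos) == 0 or end <= start:
        return 0
    return int(
        np.searchsorted(pos, end, side="left") - np.searchsorted(pos, start, side="left")
    )


def _local_edges_metagene(span: int) -> np.ndarray:
    """101 integer bin edges in gene-local 5'->3' coordinates (0 = TSS)."""
    up = FLANK_BIN_BP * np.arange(-FLANK_BINS, 0)
    body = np.floor(span * np.arange(BODY_BINS + 1) / BODY_BINS).astype(np.int64)
    down = span + FLANK_BIN_BP * np.arange(1, FLANK_BINS + 1)
    return np.concatenate([up, body, down])


def _counts_for_edges(
    pos: Optional[np.ndarray], gene: GeneModel, local_edges: np.ndarray, chrom_len: int
) -> Tuple[np.ndarray, bool]:
    """Counts per bin from local edges, strand-mapped to genomic coordinates.

    Local bin [a, b) maps to genomic [start+a, start+b) on '+' and to
    [end-b, end-a) on '-'; both directions use the same integer local
    edges, so a mirrored landscape gives identical rows.
    """
    e = np.asarray(local_edges, dtype=np.int64)
    if gene.strand == "+":
        lo, hi = gene.start + e[:-1], gene.start + e[1:]
    else:
        lo, hi = gene.end - e[1:], gene.end - e[:-1]
    clipped = bool(lo.min() < 0 or hi.max() > chrom_len)
    lo = np.clip(lo, 0, chrom_len)
    hi = np.clip(hi, 0, chrom_len)
    counts = np.array(
        [_count_range(pos, int(a), int(b)) for a, b in zip(lo, hi)], dtype=np.int64
    )
    return counts, clipped


def metagene_matrix(
    genes: Sequence[GeneModel],
    chip: TagLibrary,
    input_lib: TagLibrary,
    chrom_sizes: ChromSizes,
    pseudo: float = 1.0,
) -> ProfileMatrix:
    """25 upstream + 50 body + 25 downstream bins per gene, 5'->3'.

    Genes spanning < 500 bp are dropped (counted in ``n_excluded``).
    """
    kept = [g for g in genes if g.span >= MIN_GENE_SPAN]
    n_excluded = len(genes) - len(kept)
    if n_excluded:
        log.info("metagene_matrix: excluded %d genes shorter than %d bp", n_excluded, MIN_GENE_SPAN)
    scale = chip.total_tags / max(1, input_lib.total_tags)
    values = np.empty((len(kept), 100))
    clipped_flags = np.zeros(len(kept), dtype=bool)
    for i, g in enumerate(kept):
        edges = _local_edges_metagene(g.span)
        chip_c, clip1 = _counts_for_edges(
            chip.positions.get(g.chrom), g, edges, chrom_sizes[g.chrom]
        )
        inp_c, _ = _counts_for_edges(
            input_lib.positions.get(g.chrom), g, edges, chrom_sizes[g.chrom]
        )
        values[i] = enrichment_ratio(chip_c, inp_c, scale, pseudo)
        clipped_flags[i] = clip1
    return ProfileMatrix(
        layout=METAGENE_100,
        gene_ids=[g.gene_id for g in kept],
        values=values,
        clipped=clipped_flags,
        n_excluded=n_excluded,
    )


def _local_edges_tss() -> np.ndarray:
    half = TSS_BINS // 2 * TSS_BIN_BP
    return np.arange(-half, half + 1, TSS_BIN_BP)


def tss_matrix(
    genes: Sequence[GeneModel],
    chip: TagLibrary,
    input_lib: TagLibrary,
    chrom_sizes: ChromSizes,
    pseudo: float = 1.0,
) -> ProfileMatrix:
    """Fifty 200-bp bins spanning [tss-5kb, tss+5kb) in gene orientation.

    Bin 24 covers [tss-200, tss); bin 25 covers [tss, tss+200).
    """
    scale = chip.total_tags / max(1, input_lib.total_tags)
    values = np.empty((len(genes), TSS_BINS))
    clipped_flags = np.zeros(len(genes), dtype=bool)
    edges = _local_edges_tss()
    for i, g in enumerate(genes):
        chip_c, clip1 = _counts_for_edges(
            chip.positions.get(g.chrom), g, edges, chrom_sizes[g.chrom]
        )
        inp_c, _ = _counts_for_edges(
            input_lib.positions.get(g.chrom), g, edges, chrom_sizes[g.chrom]
        )
        values[i] = enrichment_ratio(chip_c, inp_c, scale, pseudo)
        clipped_flags[i] = clip1
    return ProfileMatrix(
        layout=TSS_50,
        gene_ids=[g.gene_id for g in genes],
        values=values,
        clipped=clipped_flags,
    )


def total_tss_enrichment(matrix: ProfileMatrix) -> pd.Series:
    """Per-gene sum of the 50 TSS-bin enrichments."""
    if matrix.layout != TSS_50:
        raise TypeError(f"total_tss_enrichment needs a {TSS_50} matrix, got {matrix.layout}")
    return pd.Series(matrix.values.sum(axis=1), index=matrix.gene_ids, name="total_enrichment")


def average_profile(
    matrix: ProfileMatrix, gene_subset: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-bin mean and quartiles over a gene subset (all genes if None)."""
    if gene_subset is None:
        rows = matrix.values
    else:
        index = {gid: i for i, gid in enumerate(matrix.gene_ids)}
        idx = [index[g] for g in gene_subset if g in index]
        if len(idx) == 0:
            warnings.warn("average_profile: empty gene subset", stacklevel=2)
            n_bins = matrix.values.shape[1]
            nan = np.full(n_bins, np.nan)
            return pd.DataFrame({"mean": nan, "q25": nan, "median": nan, "q75": nan})
        rows = matrix.values[idx]
    return pd.DataFrame(
        {
            "mean": rows.mean(axis=0),
            "q25": np.percentile(rows, 25, axis=0),
            "median": np.percentile(rows, 50, axis=0),
            "q75": np.percentile(rows, 75, axis=0),
        }
    )
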