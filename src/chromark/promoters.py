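"""Promoter-window mark calling, RPKM, and expression categorization.

A mark is "present" at a promoter when its merged islands cover at least
10% of the -1 kb/+2 kb strand-aware window around the TSS (the denominator
is the window length by default; the peak-relative alternative is exposed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ChromSizes, GeneModel, GenomicInterval, covered_bp, merge_intervals

__all__ = [
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "CATEGORIES",
    "PromoterMarkCalls",
    "promoter_window",
    "call_promoter_marks",
    "rpkm",
    "rpkm_table",
    "select_representative_transcript",
    "expression_categories",
    "class_label",
]

log = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1_000
PROMOTER_DOWNSTREAM = 2_000

CATEGORIES = ("NOT_EXPRESSED", "LOW", "INTERMEDIATE", "HIGH")


def promoter_window(
    gene: GeneModel, chrom_sizes: Optional[ChromSizes] = None
) -> Tuple[GenomicInterval, bool]:
    """Strand-aware [-1 kb, +2 kb) window around the TSS, clipped to bounds."""
    if gene.strand == "+":
        start, end = gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM
    else:
        start, end = gene.tss - PROMOTER_DOWNSTREAM, gene.tss + PROMOTER_UPSTREAM
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_sizes is not None and end > chrom_sizes[gene.chrom]:
        end, clipped = chrom_sizes[gene.chrom], True
    return GenomicInterval(gene.chrom, start, end, name=gene.gene_id), clipped


def class_label(has_ub: bool, has_k4: bool, has_k27: bool) -> str:
    """Canonical label for one of the 8 mark combinations."""
    parts = []
    if has_ub:
        parts.append("Ub")
    if has_k4:
        parts.append("K4")
    if has_k27:
        parts.append("K27")
    return "+".join(parts) if parts else "none"


@dataclass
class PromoterMarkCalls:
    """Per-gene boolean mark presence over the promoter window."""

    table: pd.DataFrame  # index gene_id; has_H2AK119Ub/has_H3K4me3/has_H3K27me3/label

    def genes_with(self, **marks: bool) -> List[str]:
        mask = np.ones(len(self.table), dtype=bool)
        for key, wanted in marks.items():
            mask &= self.table[key].to_numpy() == wanted
        return list(self.table.index[mask])


def call_promoter_marks(
    genes: Sequence[GeneModel],
    islands_per_mark: Dict[str, Sequence[GenomicInterval]],
    chrom_sizes: Optional[ChromSizes] = None,
    min_frac: float = 0.10,
    denominator: str = "window",
) -> PromoterMarkCalls:
    """Call mark presence per promoter by fractional island coverage.

    ``denominator="window"`` (default): covered bp / window length >= min_frac.
    ``denominator="peak"``: overlap with some single island / island length
    >= min_frac.
    """
    if denominator not in ("window", "peak"):
        raise ValueError("denominator must be 'window' or 'peak'")
    merged_per_mark: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    for mark, islands in islands_per_mark.items():
        if len(islands) == 0:
            warnings.warn(f"no islands for mark {mark}: all calls false", stacklevel=2)
        merged = merge_intervals(islands)
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        merged_per_mark[mark] = by_chrom
    records = {}
    for g in genes:
        window, _ = promoter_window(g, chrom_sizes)
        row = {}
        for mark, by_chrom in merged_per_mark.items():
            ivs = by_chrom.get(g.chrom, [])
            if denominator == "window":
                present = covered_bp(window, ivs) / len(window) >= min_frac
            else:
                present = any(
                    (min(iv.end, window.end) - max(iv.start, window.start)) / len(iv)
                    >= min_frac
                    for iv in ivs
                    if min(iv.end, window.end) > max(iv.start, window.start)
                )
            row[f"has_{mark}"] = bool(present)
        records[g.gene_id] = row
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "gene_id"
    from .simulate import MARK_K4, MARK_K27, MARK_UB

    for col in (f"has_{MARK_UB}", f"has_{MARK_K4}", f"has_{MARK_K27}"):
        if col not in table.columns:
            table[col] = False
    table["label"] = [
        class_label(r[f"has_{MARK_UB}"], r[f"has_{MARK_K4}"], r[f"has_{MARK_K27}"])
        for _, r in table.iterrows()
    ]
    return PromoterMarkCalls(table=table)


def rpkm(count: float, exonic_length: int, library_size: int) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if exonic_length < 1:
        raise ValueError("exonic_length must be >= 1")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    return count * 1e9 / (exonic_length * library_size)


def rpkm_table(counts: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-sample RPKM for every gene in the counts matrix."""
    lengths = pd.Series({g.gene_id: g.exonic_length for g in genes})
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"genes missing from annotation: {list(missing)[:5]}")
    lengths = lengths.reindex(counts.index)
    lib_sizes = counts.sum(axis=0)
    return counts * 1e9 / np.outer(lengths, lib_sizes)


def select_representative_transcript(
    transcript_expression: Dict[str, Dict[str, float]],
) -> Dict[str, str]:
    """Per gene, the transcript with the highest expression estimate.

    Ties break lexicographically by transcript id (logged).
    """
    out = {}
    for gene_id, estimates in transcript_expression.items():
        if not estimates:
            raise ValueError(f"gene {gene_id} has no transcripts")
        best = max(sorted(estimates), key=lambda t: estimates[t])
        tied = [t for t, v in estimates.items() if v == estimates[best]]
        if len(tied) > 1:
            log.info(
                "gene %s: tie among transcripts %s, keeping %s", gene_id, tied, best
            )
        out[gene_id] = best
    return out


def expression_categories(
    mean_rpkm: pd.Series, not_expressed_threshold: float = 0.5
) -> pd.Series:
    """Four categories: below threshold, then ascending-rank tertiles.

    Expressed genes are ranked ascending by mean RPKM (ties broken by the
    stable input order) and split at the 1/3 and 2/3 rank boundaries.
    """
    if not_expressed_threshold < 0:
        raise ValueError("threshold must be >= 0")
    cats = pd.Series("NOT_EXPRESSED", index=mean_rpkm.index, name="category")
    expressed = mean_rpkm.index[mean_rpkm >= not_expressed_threshold]
    n = len(expressed)
    if n < 3:
        raise ValueError(f"only {n} expressed genes; need at least 3 for tertiles")
    order = np.argsort(mean_rpkm.loc[expressed].to_numpy(), kind="stable")
    lo, hi = n // 3, (2 * n) // 3
    ranked = expressed[order]
    cats.loc[ranked[:lo]] = "LOW"
    cats.loc[ranked[lo:hi]] = "INTERMEDIATE"
    cats.loc[ranked[hi:]] = "HIGH"
    return cats
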