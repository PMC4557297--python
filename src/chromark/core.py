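"""Domain types, genomic-interval arithmetic and plain-text genomic I/O.

Coordinates are 0-based, half-open ``[start, end)`` everywhere (BED
convention), including the gene table.  Touching intervals merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ChromSizes",
    "TagLibrary",
    "BedParseError",
    "overlap_bp",
    "merge_intervals",
    "fraction_regions_overlapping",
    "covered_bp",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_counts_table",
    "write_bedgraph",
    "read_bedgraph",
]


class BedParseError(ValueError):
    """Raised on malformed BED / gene-table / bedGraph input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TTS.

    ``tss``/``tts`` are the 5'/3' ends: for '+' genes tss == start and
    tts == end; for '-' genes tss == end and tts == start.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exonic_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.exonic_length < 1:
            raise ValueError(f"gene {self.gene_id}: exonic_length < 1")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def span(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id, strand=self.strand)


class ChromSizes(dict):
    """Mapping chromosome name -> length (bp)."""

    def __init__(self, sizes: Dict[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        super().__init__(sizes)

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self:
            raise ValueError(f"unknown chromosome {iv.chrom}")
        if iv.end > self[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self[iv.chrom]}"
            )


class TagLibrary:
    """Deduplicated fragment midpoints, sorted per chromosome."""

    def __init__(self, positions: Dict[str, np.ndarray], label: str = ""):
        self.positions: Dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError("positions must be 1-D per chromosome")
            if np.any(arr < 0):
                raise ValueError(f"negative tag position on {chrom}")
            self.positions[chrom] = np.sort(arr)
        self.label = label

    @property
    def total_tags(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))

    def chroms(self) -> List[str]:
        return sorted(self.positions)

    def validate(self, chrom_sizes: ChromSizes) -> None:
        for chrom, pos in self.positions.items():
            if chrom not in chrom_sizes:
                raise ValueError(f"tag library chromosome {chrom} not in chrom sizes")
            if len(pos) and pos[-1] >= chrom_sizes[chrom]:
                raise ValueError(
                    f"tag at {chrom}:{int(pos[-1])} beyond chromosome end "
                    f"{chrom_sizes[chrom]}"
                )

    @classmethod
    def from_bed(cls, stream: TextIO, label: str = "") -> "TagLibrary":
        """Build a library from BED fragments, storing midpoints."""
        by_chrom: Dict[str, list] = {}
        for iv in read_bed(stream):
            by_chrom.setdefault(iv.chrom, []).append((iv.start + iv.end) // 2)
        return cls({c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}, label=label)

    def to_bed(self, stream: TextIO, fragment_size: int = 1) -> None:
        half = fragment_size // 2
        for chrom in self.chroms():
            for p in self.positions[chrom]:
                start = max(0, int(p) - half)
                stream.write(f"{chrom}\t{start}\t{start + max(1, fragment_size)}\n")


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases between two intervals; 0 if on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(regions: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Minimal disjoint set covering the same bases; touching intervals merge."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    merged: List[GenomicInterval] = []
    for iv in regions:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def covered_bp(region: GenomicInterval, merged: Sequence[GenomicInterval]) -> int:
    """Bases of ``region`` covered by a merged (disjoint, sorted) interval set."""
    total = 0
    for iv in merged:
        if iv.chrom != region.chrom:
            continue
        if iv.start >= region.end:
            break
        total += max(0, min(iv.end, region.end) - max(iv.start, region.start))
    return total


def fraction_regions_overlapping(
    A: Sequence[GenomicInterval],
    B: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> Tuple[float, np.ndarray]:
    """Fraction of regions in A with >= min_bp bases covered by merged B.

    Returns ``(fraction, flags)``; with empty ``A`` the fraction is NaN and a
    warning is emitted.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    merged = merge_intervals(B)
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    flags = np.zeros(len(A), dtype=bool)
    for i, region in enumerate(A):
        flags[i] = covered_bp(region, by_chrom.get(region.chrom, [])) >= min_bp
    if len(A) == 0:
        warnings.warn("fraction_regions_overlapping: empty region set A", stacklevel=2)
        return float("nan"), flags
    return float(flags.mean()), flags


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(stream: TextIO) -> List[GenomicInterval]:
    """Read BED3+ into intervals, preserving name/score/strand when present."""
    out: List[GenomicInterval] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"line {lineno}: fewer than 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
        if start < 0 or start >= end:
            raise BedParseError(f"line {lineno}: invalid interval {chrom}:{start}-{end}")
        name = fields[3] if len(fields) > 3 else None
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else None
        out.append(GenomicInterval(chrom, start, end, name=name, score=score, strand=strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], stream: TextIO) -> None:
    for iv in intervals:
        cols = [iv.chrom, str(iv.start), str(iv.end)]
        if iv.name is not None or iv.score is not None or iv.strand is not None:
            cols.append(iv.name if iv.name is not None else ".")
        if iv.score is not None or iv.strand is not None:
            cols.append(f"{iv.score:g}" if iv.score is not None else ".")
        if iv.strand is not None:
            cols.append(iv.strand)
        stream.write("\t".join(cols) + "\n")


_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "exonic_length"]


def read_gene_table(stream: TextIO) -> List[GeneModel]:
    """Read the tab-separated gene table (header: gene_id chrom start end strand exonic_length)."""
    header = stream.readline().rstrip("\n").split("\t")
    if header[: len(_GENE_COLUMNS)] != _GENE_COLUMNS:
        raise BedParseError(
            f"gene table header must start with {_GENE_COLUMNS}, got {header}"
        )
    genes: List[GeneModel] = []
    seen = set()
    for lineno, line in enumerate(stream, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        gene_id = f[0]
        if gene_id in seen:
            raise BedParseError(f"line {lineno}: duplicated gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            start, end, exonic = int(f[2]), int(f[3]), int(f[5])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer field") from exc
        strand = f[4]
        if strand not in ("+", "-"):
            raise BedParseError(f"line {lineno}: unknown strand {strand!r}")
        genes.append(GeneModel(gene_id, f[1], strand, start, end, exonic))
    return genes


def write_gene_table(genes: Iterable[GeneModel], stream: TextIO) -> None:
    stream.write("\t".join(_GENE_COLUMNS) + "\n")
    for g in genes:
        stream.write(
            f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.exonic_length}\n"
        )


def read_counts_table(stream: TextIO):
    """Read a genes x samples counts TSV (gene_id index, header row) via pandas."""
    import pandas as pd

    df = pd.read_csv(stream, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise BedParseError(f"duplicated gene ids in counts table: {dups}")
    return df


def write_bedgraph(
    values: Dict[str, np.ndarray],
    bin_size: int,
    chrom_sizes: ChromSizes,
    stream: TextIO,
    omit_zero: bool = True,
) -> None:
    """Write fixed-bin values as bedGraph; zero bins omitted by default."""
    for chrom in sorted(values):
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom}")
        arr = np.asarray(values[chrom])
        if len(arr) * bin_size < chrom_sizes[chrom] - bin_size + 1 or (
            (len(arr) - 1) * bin_size >= chrom_sizes[chrom]
        ):
            raise ValueError(
                f"{chrom}: {len(arr)} bins of {bin_size} bp do not tile "
                f"chromosome of length {chrom_sizes[chrom]}"
            )
        for k, v in enumerate(arr):
            if omit_zero and v == 0:
                continue
            start = k * bin_size
            end = min((k + 1) * bin_size, chrom_sizes[chrom])
            stream.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def read_bedgraph(stream: TextIO, bin_size: int, chrom_sizes: ChromSizes) -> Dict[str, np.ndarray]:
    """Inverse of :func:`write_bedgraph` for fixed-bin tracks (missing bins = 0)."""
    out = {
        chrom: np.zeros(-(-length // bin_size)) for chrom, length in chrom_sizes.items()
    }
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(_SKIP_PREFIXES):
            continue
        chrom, start, end, value = line.split("\t")
        start = int(start)
        if start % bin_size != 0:
            raise BedParseError(f"line {lineno}: start {start} not on a {bin_size}-bp grid")
        out[chrom][start // bin_size] = float(value)
    return out
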