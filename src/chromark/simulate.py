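"""Synthetic chromatin landscapes with planted ground truth.

Generates a toy annotated genome, plants broad co-occurring repressive
domains and punctate TSS peaks per gene class, samples ChIP/input tag
libraries from a piecewise-constant intensity (total-count-conditioned so
library sizes are exact), and draws two-condition negative-binomial
expression counts in which only the H2AK119Ub+H3K4me3-bearing classes carry
a planted upregulation under depletion.  Everything is a pure function of
the configuration, including its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    TagLibrary,
    read_bed,
    write_bed,
)

__all__ = [
    "MARK_K4", "MARK_UB", "MARK_K27",
    "GENE_CLASSES", "CLASS_NAMES",
    "GeneClass", "SimulationConfig", "SyntheticTruth", "SimulatedDataset",
    "simulate_annotation", "plant_domains", "simulate_tag_library",
    "simulate_expression", "simulate_dataset", "write_truth", "load_truth",
]

MARK_K4 = "H3K4me3"
MARK_UB = "H2AK119Ub"
MARK_K27 = "H3K27me3"
MARKS = (MARK_UB, MARK_K4, MARK_K27)


@dataclass(frozen=True)
class GeneClass:
    name: str
    marks: FrozenSet[str]
    baseline_mean: float
    perturbation_log2fc: float


# class roster: active, repressed, Ub+K4, bivalent+Ub, unmarked
GENE_CLASSES: Dict[str, GeneClass] = {
    "ACTIVE_K4": GeneClass("ACTIVE_K4", frozenset({MARK_K4}), 500.0, 0.0),
    "REPRESSED_UB_K27": GeneClass(
        "REPRESSED_UB_K27", frozenset({MARK_UB, MARK_K27}), 0.5, 0.0
    ),
    "K4_UB": GeneClass("K4_UB", frozenset({MARK_K4, MARK_UB}), 40.0, 2.0),
    "ALL_THREE": GeneClass(
        "ALL_THREE", frozenset({MARK_K4, MARK_UB, MARK_K27}), 40.0, 2.0
    ),
    "UNMARKED": GeneClass("UNMARKED", frozenset(), 0.3, 0.0),
}
CLASS_NAMES = tuple(GENE_CLASSES)


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    class_proportions: Tuple[float, ...] = (0.25, 0.40, 0.15, 0.10, 0.10)
    co_occurrence_frac: float = 0.74
    gene_min_length: int = 2_000
    gene_max_length: int = 8_000
    spacing_min: int = 6_000
    spacing_max: int = 12_000
    domain_flank_min: int = 200
    domain_flank_max: int = 1_000
    k4_peak_halfwidth: int = 1_000
    enrichment_fold: float = 8.0
    background_density: float = 2.5  # tags per kb
    n_tags: Optional[int] = None  # None: use the expected total intensity
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    depletion_factor_ub: float = 0.90
    depletion_factor_k27: float = 0.50
    gene_mean_log2_sd: float = 0.5
    perturbation_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != len(CLASS_NAMES):
            raise ValueError(f"need {len(CLASS_NAMES)} class proportions")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        if np.any(props < 0):
            raise ValueError("class proportions must be non-negative")
        if not (0.0 <= self.co_occurrence_frac <= 1.0):
            raise ValueError("co_occurrence_frac must lie in [0, 1]")
        for name in ("depletion_factor_ub", "depletion_factor_k27"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("enrichment_fold", "background_density", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gene_min_length < 600:
            raise ValueError("gene_min_length must be >= 600")

    def spawn_rng(self, stream: str) -> np.random.Generator:
        """Deterministic substream for a named stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAM_IDS[stream],))
        )


_STREAM_IDS = {
    "annotation": 0,
    "domains": 1,
    "tags": 2,
    "expression": 3,
}


@dataclass
class SyntheticTruth:
    domains: Dict[str, List[GenomicInterval]]
    gene_classes: Dict[str, str]
    gene_marks: Dict[str, FrozenSet[str]]  # effective marks incl. coin-flip K27
    gene_log2fc: Dict[str, float]
    seed: int


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    chrom_sizes: ChromSizes
    genes: List[GeneModel]
    truth: SyntheticTruth
    chip: Dict[str, TagLibrary]  # baseline ChIP per mark
    input_: TagLibrary
    counts: pd.DataFrame
    condition_labels: Tuple[str, ...] = ("control", "depleted")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[ChromSizes, List[GeneModel], Dict[str, str]]:
    """Place non-overlapping genes with random strand/length and assign classes."""
    rng = rng or config.spawn_rng("annotation")
    chrom_sizes = ChromSizes(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    worst_per_gene = config.gene_max_length + config.spacing_max
    if config.n_genes * worst_per_gene > config.n_chroms * config.chrom_length:
        raise ValueError(
            f"cannot pack {config.n_genes} genes of up to "
            f"{worst_per_gene} bp each into the genome; enlarge chrom_length"
        )
    genes: List[GeneModel] = []
    chrom_names = sorted(chrom_sizes)
    per_chrom = -(-config.n_genes // config.n_chroms)
    gi = 0
    for chrom in chrom_names:
        cursor = int(rng.integers(config.spacing_min, config.spacing_max + 1))
        for _ in range(per_chrom):
            if gi >= config.n_genes:
                break
            length = int(rng.integers(config.gene_min_length, config.gene_max_length + 1))
            if cursor + length + config.spacing_min > config.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=cursor,
                    end=cursor + length,
                    exonic_length=length,
                )
            )
            cursor += length + int(rng.integers(config.spacing_min, config.spacing_max + 1))
    if gi < config.n_genes:
        raise ValueError(
            f"could only place {gi} of {config.n_genes} genes; enlarge the genome"
        )
    props = np.asarray(config.class_proportions, dtype=float)
    labels = rng.choice(len(CLASS_NAMES), size=config.n_genes, p=props)
    classes = {g.gene_id: CLASS_NAMES[k] for g, k in zip(genes, labels)}
    return chrom_sizes, genes, classes


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

def plant_domains(
    genes: Sequence[GeneModel],
    classes: Dict[str, str],
    config: SimulationConfig,
    chrom_sizes: ChromSizes,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, List[GenomicInterval]], SyntheticTruth]:
    """Plant per-mark domains and record the effective per-gene mark truth.

    Genes whose class carries H2AK119Ub get a broad domain over the gene
    body plus drawn flanks; a coincident H3K27me3 domain is planted always
    when the class mandates it, otherwise with probability
    ``co_occurrence_frac``.  H3K4me3 is a punctate TSS interval.
    """
    rng = rng or config.spawn_rng("domains")
    domains: Dict[str, List[GenomicInterval]] = {m: [] for m in MARKS}
    gene_marks: Dict[str, FrozenSet[str]] = {}
    gene_log2fc: Dict[str, float] = {}

    def draw_flank() -> int:
        return int(rng.integers(config.domain_flank_min, config.domain_flank_max + 1))

    def clipped(chrom: str, start: int, end: int) -> GenomicInterval:
        length = chrom_sizes[chrom]
        return GenomicInterval(chrom, max(0, start), min(length, end))

    for g in genes:
        cls = GENE_CLASSES[classes[g.gene_id]]
        marks = set(cls.marks)
        if MARK_UB in marks:
            domains[MARK_UB].append(
                clipped(g.chrom, g.start - draw_flank(), g.end + draw_flank())
            )
            if MARK_K27 in marks:
                domains[MARK_K27].append(
                    clipped(g.chrom, g.start - draw_flank(), g.end + draw_flank())
                )
            elif rng.random() < config.co_occurrence_frac:
                marks.add(MARK_K27)
                domains[MARK_K27].append(
                    clipped(g.chrom, g.start - draw_flank(), g.end + draw_flank())
                )
        elif MARK_K27 in marks:
            domains[MARK_K27].append(
                clipped(g.chrom, g.start - draw_flank(), g.end + draw_flank())
            )
        if MARK_K4 in marks:
            h = config.k4_peak_halfwidth
            domains[MARK_K4].append(clipped(g.chrom, g.tss - h, g.tss + h))
        gene_marks[g.gene_id] = frozenset(marks)
        lfc = cls.perturbation_log2fc
        if lfc > 0:
            lfc = config.perturbation_log2fc
        gene_log2fc[g.gene_id] = lfc
    for m in MARKS:
        domains[m].sort(key=lambda iv: (iv.chrom, iv.start))
    truth = SyntheticTruth(
        domains=domains,
        gene_classes=dict(classes),
        gene_marks=gene_marks,
        gene_log2fc=gene_log2fc,
        seed=config.seed,
    )
    return domains, truth


# ---------------------------------------------------------------------------
# tag libraries
# ---------------------------------------------------------------------------

def _segments_for_chrom(
    length: int, domain_ivs: List[GenomicInterval]
) -> List[Tuple[int, int, bool]]:
    """Alternating (start, end, in_domain) segments tiling the chromosome."""
    from .core import merge_intervals

    merged = merge_intervals(domain_ivs) if domain_ivs else []
    segments: List[Tuple[int, int, bool]] = []
    cursor = 0
    for iv in merged:
        if iv.start > cursor:
            segments.append((cursor, iv.start, False))
        segments.append((iv.start, min(iv.end, length), True))
        cursor = min(iv.end, length)
    if cursor < length:
        segments.append((cursor, length, False))
    return segments


def simulate_tag_library(
    domains: Sequence[GenomicInterval],
    config: SimulationConfig,
    chrom_sizes: ChromSizes,
    condition: str = "baseline",
    depletion_factor: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    label: str = "chip",
) -> Tuple[TagLibrary, TagLibrary]:
    """Sample a ChIP library and a matched-depth uniform input library.

    Intensity is ``background_density`` outside domains and
    ``background_density * enrichment_fold`` inside; under the depleted
    condition the in-domain intensity is multiplied by
    ``1 - depletion_factor``.  The total tag count is fixed (multinomial
    over segments), so library sizes are exact.
    """
    if condition not in ("baseline", "depleted"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = rng or config.spawn_rng("tags")
    bg = config.background_density / 1000.0  # tags per bp
    fold = config.enrichment_fold
    if condition == "depleted":
        fold = fold * (1.0 - depletion_factor)
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in domains:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    seg_chroms: List[str] = []
    seg_bounds: List[Tuple[int, int]] = []
    seg_weights: List[float] = []
    for chrom in sorted(chrom_sizes):
        for start, end, in_domain in _segments_for_chrom(
            chrom_sizes[chrom], by_chrom.get(chrom, [])
        ):
            rate = bg * fold if in_domain else bg
            seg_chroms.append(chrom)
            seg_bounds.append((start, end))
            seg_weights.append(rate * (end - start))
    weights = np.asarray(seg_weights)
    total_intensity = weights.sum()
    if total_intensity <= 0:
        raise ValueError("total tag intensity is zero; check densities")
    n_tags = config.n_tags if config.n_tags is not None else int(round(total_intensity))
    seg_counts = rng.multinomial(n_tags, weights / total_intensity)
    chip_pos: Dict[str, List[np.ndarray]] = {c: [] for c in chrom_sizes}
    for chrom, (start, end), k in zip(seg_chroms, seg_bounds, seg_counts):
        if k:
            chip_pos[chrom].append(rng.integers(start, end, size=k))
    chip = TagLibrary(
        {
            c: np.concatenate(v) if v else np.empty(0, dtype=np.int64)
            for c, v in chip_pos.items()
        },
        label=label,
    )
    # input: uniform over the genome at matching depth
    lengths = np.array([chrom_sizes[c] for c in sorted(chrom_sizes)], dtype=float)
    chrom_counts = rng.multinomial(n_tags, lengths / lengths.sum())
    input_lib = TagLibrary(
        {
            c: rng.integers(0, chrom_sizes[c], size=k)
            for c, k in zip(sorted(chrom_sizes), chrom_counts)
        },
        label="input",
    )
    return chip, input_lib


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion alpha (var = m + a m^2)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        r = 1.0 / dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_expression(
    genes: Sequence[GeneModel],
    classes: Dict[str, str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    gene_log2fc: Optional[Dict[str, float]] = None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Two-condition NB counts matrix plus the planted log2FC per gene."""
    rng = rng or config.spawn_rng("expression")
    n = len(genes)
    base_means = np.empty(n)
    lfc = np.empty(n)
    for i, g in enumerate(genes):
        cls = GENE_CLASSES[classes[g.gene_id]]
        base_means[i] = cls.baseline_mean
        if gene_log2fc is not None:
            lfc[i] = gene_log2fc[g.gene_id]
        else:
            lfc[i] = (
                config.perturbation_log2fc if cls.perturbation_log2fc > 0 else 0.0
            )
    # gene-level biological variation around the class mean
    base_means = base_means * 2.0 ** rng.normal(0.0, config.gene_mean_log2_sd, size=n)
    depleted_means = base_means * 2.0**lfc
    cols = {}
    for j in range(config.n_replicates):
        cols[f"control_{j + 1}"] = _nb_draw(rng, base_means, config.nb_dispersion)
    for j in range(config.n_replicates):
        cols[f"depleted_{j + 1}"] = _nb_draw(rng, depleted_means, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=[g.gene_id for g in genes])
    counts.index.name = "gene_id"
    truth_lfc = {g.gene_id: float(v) for g, v in zip(genes, lfc)}
    return counts, truth_lfc


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run annotation -> domains -> baseline ChIP + input -> expression."""
    chrom_sizes, genes, classes = simulate_annotation(config)
    domains, truth = plant_domains(genes, classes, config, chrom_sizes)
    tag_rng = config.spawn_rng("tags")
    chip: Dict[str, TagLibrary] = {}
    input_lib: Optional[TagLibrary] = None
    for mark in MARKS:
        lib, inp = simulate_tag_library(
            domains[mark],
            config,
            chrom_sizes,
            condition="baseline",
            rng=tag_rng,
            label=mark,
        )
        chip[mark] = lib
        if input_lib is None:
            input_lib = inp
    counts, _ = simulate_expression(
        genes, classes, config, gene_log2fc=truth.gene_log2fc
    )
    return SimulatedDataset(
        config=config,
        chrom_sizes=chrom_sizes,
        genes=genes,
        truth=truth,
        chip=chip,
        input_=input_lib,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# truth persistence
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for mark, ivs in truth.domains.items():
        with open(directory / f"domains_{mark}.bed", "w") as fh:
            write_bed(sorted(ivs, key=lambda i: (i.chrom, i.start)), fh)
    with open(directory / "gene_truth.tsv", "w") as fh:
        fh.write("gene_id\tclass\tmarks\tlog2fc\n")
        for gid in sorted(truth.gene_classes):
            marks = ",".join(sorted(truth.gene_marks[gid]))
            fh.write(
                f"{gid}\t{truth.gene_classes[gid]}\t{marks}\t"
                f"{truth.gene_log2fc[gid]:g}\n"
            )
    with open(directory / "meta.json", "w") as fh:
        json.dump({"seed": truth.seed, "marks": list(truth.domains)}, fh)


def load_truth(directory) -> SyntheticTruth:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"truth metadata not found: {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    domains: Dict[str, List[GenomicInterval]] = {}
    for mark in meta["marks"]:
        path = directory / f"domains_{mark}.bed"
        if not path.exists():
            raise FileNotFoundError(f"truth domain file not found: {path}")
        with open(path) as fh:
            domains[mark] = read_bed(fh)
    gene_classes: Dict[str, str] = {}
    gene_marks: Dict[str, FrozenSet[str]] = {}
    gene_log2fc: Dict[str, float] = {}
    truth_path = directory / "gene_truth.tsv"
    if not truth_path.exists():
        raise FileNotFoundError(f"gene truth file not found: {truth_path}")
    with open(truth_path) as fh:
        header = fh.readline()
        for line in fh:
            gid, cls, marks, lfc = line.rstrip("\n").split("\t")
            gene_classes[gid] = cls
            gene_marks[gid] = frozenset(m for m in marks.split(",") if m)
            gene_log2fc[gid] = float(lfc)
    return SyntheticTruth(
        domains=domains,
        gene_classes=gene_classes,
        gene_marks=gene_marks,
        gene_log2fc=gene_log2fc,
        seed=meta["seed"],
    )
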