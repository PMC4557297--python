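"""End-to-end orchestration: simulate -> call islands -> profile ->
classify -> differential expression -> association report.

One YAML config block drives the run; a resolved copy of the config is
written into the output directory and all TSV outputs are byte-stable for
a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .assoc import mark_cooccurrence, stratified_expression, derepression_fraction
from .core import (
    ChromSizes,
    TagLibrary,
    read_bed,
    read_counts_table,
    read_gene_table,
    write_gene_table,
)
from .diffexpr import run_de
from .islands import IslandCallParams, call_islands, write_island_bed, write_island_stats
from .profiles import metagene_matrix, tss_matrix
from .promoters import call_promoter_marks, expression_categories, rpkm_table

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "simulation": {},  # SimulationConfig overrides; presence selects simulation mode
    "islands": {"fdr": 0.01, "p0": 0.2, "effective_genome_fraction": 1.0},
    "classify": {
        "min_frac": 0.10,
        "denominator": "window",
        "not_expressed_threshold": 0.5,
    },
    "de": {"fold_threshold": 2.0, "p_threshold": 0.05},
}


def _merge(base: Dict, override: Optional[Dict]) -> Dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path) -> Dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_all(config: Dict, outdir) -> Path:
    """Execute every stage; returns the run directory.

    In simulation mode (config has a ``simulation`` block) everything is
    generated from the seed; in real-data mode the config must provide
    paths under ``real``: genes, chrom_sizes, chip (mark -> BED), input,
    counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = _merge(DEFAULT_CONFIG, config)
    t0 = time.time()
    log_lines = []

    def stage(msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {msg}")
        log.info(msg)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    simulated = not config.get("real")

    if simulated:
        sim_kwargs = dict(config.get("simulation") or {})
        sim_kwargs.setdefault("seed", config["seed"])
        if "class_proportions" in sim_kwargs:
            sim_kwargs["class_proportions"] = tuple(sim_kwargs["class_proportions"])
        sim_config = sim.SimulationConfig(**sim_kwargs)
        dataset = sim.simulate_dataset(sim_config)
        stage(f"simulated {len(dataset.genes)} genes on {sim_config.n_chroms} chromosomes")
        chrom_sizes = dataset.chrom_sizes
        genes = dataset.genes
        chip = dataset.chip
        input_lib = dataset.input_
        counts = dataset.counts
        truth_dir = outdir / "truth"
        sim.write_truth(dataset.truth, truth_dir)
        with open(outdir / "genes.tsv", "w") as fh:
            write_gene_table(genes, fh)
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        stage("wrote annotation, counts and ground truth")
    else:
        real = config.get("real") or {}
        for field in ("genes", "chrom_sizes", "chip", "input", "counts"):
            if field not in real:
                raise ValueError(f"real-data mode: missing config field real.{field}")
        with open(real["genes"]) as fh:
            genes = read_gene_table(fh)
        sizes = pd.read_csv(real["chrom_sizes"], sep="\t", header=None, names=["chrom", "length"])
        chrom_sizes = ChromSizes(dict(zip(sizes["chrom"], sizes["length"])))
        chip = {}
        for mark, path in real["chip"].items():
            with open(path) as fh:
                chip[mark] = TagLibrary.from_bed(fh, label=mark)
        with open(real["input"]) as fh:
            input_lib = TagLibrary.from_bed(fh, label="input")
        with open(real["counts"]) as fh:
            counts = read_counts_table(fh)
        stage(f"loaded {len(genes)} genes and {len(chip)} chip libraries")

    # --- island calling per mark -------------------------------------------
    islands_dir = outdir / "islands"
    islands_dir.mkdir(exist_ok=True)
    island_cfg = config["islands"]
    island_sets = {}
    for mark, lib in chip.items():
        preset_key = {
            sim.MARK_K4: "h3k4me3",
            sim.MARK_UB: "h2ak119ub",
            sim.MARK_K27: "h3k27me3",
        }.get(mark, mark.lower())
        overrides = {
            "p0": island_cfg["p0"],
            "fdr": island_cfg["fdr"],
            "effective_genome_fraction": island_cfg["effective_genome_fraction"],
            **(island_cfg.get(preset_key) or {}),
        }
        params = IslandCallParams.for_mark(preset_key, **overrides)
        result = call_islands(lib, input_lib, params, chrom_sizes, label=mark)
        island_sets[mark] = result
        with open(islands_dir / f"{mark}.bed", "w") as fh:
            write_island_bed(result, fh)
        with open(islands_dir / f"{mark}.stats.tsv", "w") as fh:
            write_island_stats(result, fh)
        stage(f"called {len(result)} {mark} islands (of {result.n_candidates} candidates)")

    # --- profiles -----------------------------------------------------------
    profiles_dir = outdir / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    for mark, lib in chip.items():
        mg = metagene_matrix(genes, lib, input_lib, chrom_sizes)
        _write_tsv(mg.to_frame(), profiles_dir / f"{mark}.metagene.tsv")
        ts = tss_matrix(genes, lib, input_lib, chrom_sizes)
        _write_tsv(ts.to_frame(), profiles_dir / f"{mark}.tss.tsv")
    stage("wrote metagene and TSS profile matrices")

    # --- promoter mark calls + expression ----------------------------------
    cls_cfg = config["classify"]
    calls = call_promoter_marks(
        genes,
        {m: s.intervals() for m, s in island_sets.items()},
        chrom_sizes,
        min_frac=cls_cfg["min_frac"],
        denominator=cls_cfg["denominator"],
    )
    rpkm = rpkm_table(counts, genes)
    control_cols = [c for c in counts.columns if c.startswith("control")]
    perturbed_cols = [c for c in counts.columns if not c.startswith("control")]
    if not control_cols or not perturbed_cols:
        half = len(counts.columns) // 2
        control_cols = list(counts.columns[:half])
        perturbed_cols = list(counts.columns[half:])
    mean_rpkm_control = rpkm[control_cols].mean(axis=1)
    mean_rpkm_perturbed = rpkm[perturbed_cols].mean(axis=1)
    categories = expression_categories(
        mean_rpkm_control, cls_cfg["not_expressed_threshold"]
    )
    calls_out = calls.table.copy()
    calls_out["mean_rpkm"] = mean_rpkm_control.reindex(calls_out.index)
    calls_out["category"] = categories.reindex(calls_out.index)
    _write_tsv(calls_out, outdir / "calls.tsv")
    stage("classified promoters and expression categories")

    # --- differential expression -------------------------------------------
    de_cfg = config["de"]
    groups = ["control" if c in control_cols else "depleted" for c in counts.columns]
    de = run_de(
        counts,
        groups,
        reference="control",
        fold_threshold=de_cfg["fold_threshold"],
        p_threshold=de_cfg["p_threshold"],
    )
    _write_tsv(de.table, outdir / "de.tsv")
    stage(
        f"differential expression: {len(de.up_genes())} up, {len(de.down_genes())} down"
    )

    # --- association report --------------------------------------------------
    report = stratified_expression(calls, mean_rpkm_control, mean_rpkm_perturbed, de)
    _write_tsv(report.table, outdir / "report.tsv")
    n_up, n_class, frac = derepression_fraction(calls, de)
    cooc_rows = []
    cooc = mark_cooccurrence(
        island_sets.get(sim.MARK_UB, []),
        island_sets.get(sim.MARK_K27, []),
    )
    cooc_rows.append(
        {
            "statistic": "frac_ub_regions_with_k27",
            "value": cooc["frac_a_overlapping_b"],
        }
    )
    cooc2 = mark_cooccurrence(
        island_sets.get(sim.MARK_UB, []),
        island_sets.get(sim.MARK_K4, []),
        island_sets.get(sim.MARK_K27, []),
    )
    cooc_rows.append(
        {
            "statistic": "frac_bivalent_regions_with_ub",
            "value": cooc2.get("frac_composite_with_a", float("nan")),
        }
    )
    cooc_rows.append({"statistic": "derepression_fraction", "value": frac})
    cooc_rows.append({"statistic": "derepression_n_up", "value": n_up})
    cooc_rows.append({"statistic": "derepression_n_class", "value": n_class})
    pd.DataFrame(cooc_rows).to_csv(
        outdir / "cooccurrence.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    stage("wrote association report and co-occurrence summary")

    with open(outdir / "log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return outdir
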