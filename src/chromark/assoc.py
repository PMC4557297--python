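"""Integrative statistics: mark-combination stratified expression,
Mann-Whitney U tests, box statistics, de-repression fractions and mark
co-occurrence summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, fraction_regions_overlapping, merge_intervals
from .diffexpr import DEResult
from .islands import IslandSet
from .promoters import PromoterMarkCalls, class_label

__all__ = [
    "mann_whitney_u",
    "box_stats",
    "StratifiedReport",
    "stratified_expression",
    "derepression_fraction",
    "mark_cooccurrence",
    "ALL_CLASS_LABELS",
]

EXACT_MAX_N = 16

ALL_CLASS_LABELS = tuple(
    class_label(ub, k4, k27)
    for ub in (False, True)
    for k4 in (False, True)
    for k27 in (False, True)
)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_distribution(n: int, m: int) -> Tuple[int, ...]:
    """Number of rank arrangements giving each U value for group sizes n, m.

    Classic recursion c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u) over the
    placement of the largest observation.
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_distribution(n - 1, m)
    b = _u_distribution(n, m - 1)
    size = n * m + 1
    out = [0] * size
    for u, c in enumerate(a):
        if u + m < size:
            out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed Mann-Whitney U (ties counted half).

    Exact p by enumeration of the U distribution when n+m <= 16 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    u = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n + m
    if n + m <= EXACT_MAX_N and not has_ties:
        dist = np.asarray(_u_distribution(n, m), dtype=float)
        total = dist.sum()
        k = int(round(u))
        lower = dist[: k + 1].sum() / total
        upper = dist[k:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return u, float(p)
    # normal approximation
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    N = n + m
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    from scipy import stats as sps

    p = 2.0 * sps.norm.sf(z)
    return u, float(min(1.0, p))


def box_stats(values: Sequence[float]) -> Dict[str, float]:
    """Quartiles (linear interpolation) and 1.5*IQR whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    within = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q25": float(q25),
        "median": float(med),
        "q75": float(q75),
        "lower_whisker": float(within.min()),
        "upper_whisker": float(within.max()),
    }


# ---------------------------------------------------------------------------
# stratified expression
# ---------------------------------------------------------------------------

@dataclass
class StratifiedReport:
    table: pd.DataFrame  # one row per mark-combination class


def stratified_expression(
    calls: PromoterMarkCalls,
    rpkm_control: pd.Series,
    rpkm_perturbed: pd.Series,
    de: DEResult,
) -> StratifiedReport:
    """Per mark-combination class: arcsinh-RPKM box stats for both
    conditions, Mann-Whitney p-values (vs the unmarked class and
    perturbed-vs-control within class) and UP/DOWN fractions.
    """
    genes = calls.table.index
    for series, name in ((rpkm_control, "rpkm_control"), (rpkm_perturbed, "rpkm_perturbed")):
        if not genes.isin(series.index).all():
            raise ValueError(f"{name} is missing genes present in the mark calls")
    labels = calls.table["label"]
    unmarked = list(genes[labels == "none"])
    rows = []
    for lbl in ALL_CLASS_LABELS:
        members = list(genes[labels == lbl])
        row: Dict[str, object] = {"class": lbl, "n_genes": len(members)}
        if len(members) == 0:
            rows.append(row)
            continue
        ctrl = np.arcsinh(rpkm_control.loc[members].to_numpy())
        pert = np.arcsinh(rpkm_perturbed.loc[members].to_numpy())
        for prefix, vals in (("control", ctrl), ("perturbed", pert)):
            for key, val in box_stats(vals).items():
                row[f"{prefix}_{key}"] = val
        if unmarked and lbl != "none":
            ref = np.arcsinh(rpkm_control.loc[unmarked].to_numpy())
            _, row["p_vs_unmarked"] = mann_whitney_u(ctrl, ref)
        _, row["p_perturbed_vs_control"] = mann_whitney_u(pert, ctrl)
        de_sub = de.table.loc[de.table.index.intersection(members)]
        row["fraction_up"] = float((de_sub["call"] == "UP").mean()) if len(de_sub) else np.nan
        row["fraction_down"] = float((de_sub["call"] == "DOWN").mean()) if len(de_sub) else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("class")
    return StratifiedReport(table=table)


def derepression_fraction(
    calls: PromoterMarkCalls,
    de: DEResult,
    class_predicate: Optional[Callable[[pd.Series], bool]] = None,
) -> Tuple[int, int, float]:
    """(n_up, n_class, fraction) for a promoter-class predicate.

    Default class: H2AK119Ub and H3K27me3 present, H3K4me3 absent (the
    repressed-promoter configuration).
    """
    from .simulate import MARK_K4, MARK_K27, MARK_UB

    if class_predicate is None:
        def class_predicate(row: pd.Series) -> bool:
            return (
                row[f"has_{MARK_UB}"]
                and row[f"has_{MARK_K27}"]
                and not row[f"has_{MARK_K4}"]
            )

    members = [gid for gid, row in calls.table.iterrows() if class_predicate(row)]
    n_class = len(members)
    if n_class == 0:
        warnings.warn("derepression_fraction: empty gene class", stacklevel=2)
        return 0, 0, float("nan")
    de_calls = de.table.loc[de.table.index.intersection(members), "call"]
    n_up = int((de_calls == "UP").sum())
    return n_up, n_class, n_up / n_class


# ---------------------------------------------------------------------------
# mark co-occurrence
# ---------------------------------------------------------------------------

def _intervals(obj) -> List[GenomicInterval]:
    if isinstance(obj, IslandSet):
        return obj.intervals()
    return list(obj)


def mark_cooccurrence(
    islands_a,
    islands_b,
    islands_c=None,
    min_bp: int = 1,
    composite: str = "union",
) -> Dict[str, float]:
    """Fraction of A regions overlapping B; optionally, fraction of the
    B-and-C composite regions carrying A.

    The composite ("regions carrying both B and C") is, by default, the
    merged union of B regions overlapping C and C regions overlapping B;
    ``composite="intersection"`` uses base-level B-intersect-C segments
    instead.
    """
    a = _intervals(islands_a)
    b = _intervals(islands_b)
    out: Dict[str, float] = {}
    if len(a) == 0 or len(b) == 0:
        warnings.warn("mark_cooccurrence: empty island set", stacklevel=2)
        out["frac_a_overlapping_b"] = float("nan")
    else:
        frac, _ = fraction_regions_overlapping(a, b, min_bp=min_bp)
        out["frac_a_overlapping_b"] = frac
    if islands_c is None:
        return out
    c = _intervals(islands_c)
    if len(b) == 0 or len(c) == 0:
        warnings.warn("mark_cooccurrence: empty island set for composite", stacklevel=2)
        out["frac_composite_with_a"] = float("nan")
        return out
    if composite == "union":
        _, b_flags = fraction_regions_overlapping(b, c, min_bp=min_bp)
        _, c_flags = fraction_regions_overlapping(c, b, min_bp=min_bp)
        both = [iv for iv, f in zip(b, b_flags) if f] + [
            iv for iv, f in zip(c, c_flags) if f
        ]
        composite_regions = merge_intervals(both)
    elif composite == "intersection":
        composite_regions = _base_intersection(b, c)
    else:
        raise ValueError("composite must be 'union' or 'intersection'")
    if len(composite_regions) == 0:
        warnings.warn("mark_cooccurrence: empty composite region set", stacklevel=2)
        out["frac_composite_with_a"] = float("nan")
        return out
    frac, _ = fraction_regions_overlapping(composite_regions, a, min_bp=min_bp)
    out["frac_composite_with_a"] = frac
    return out


def _base_intersection(
    b: Sequence[GenomicInterval], c: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    mb = merge_intervals(b)
    mc = merge_intervals(c)
    out: List[GenomicInterval] = []
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in mc:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in mb:
        for jv in by_chrom.get(iv.chrom, []):
            lo, hi = max(iv.start, jv.start), min(iv.end, jv.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
    return out
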