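"""Minimal two-condition negative-binomial differential expression.

Median-of-ratios size factors, method-of-moments dispersion with trend
shrinkage, a conditioned two-sided NB exact test on per-condition summed
normalized counts, and the strict >fold & p<threshold call rule (fold 2 and
fold 4 calls are both reported).  This is a declared stand-in for a full DE
package, not a re-implementation of one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .islands import adjust_bh

__all__ = [
    "DEResult",
    "size_factors",
    "estimate_dispersion",
    "nb_test",
    "classify_de",
    "run_de",
    "adjust_bh",
]

DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 10.0


@dataclass
class DEResult:
    table: pd.DataFrame  # baseMean, log2FC, p_value, q_value, call, call4

    def up_genes(self) -> List[str]:
        return list(self.table.index[self.table["call"] == "UP"])

    def down_genes(self) -> List[str]:
        return list(self.table.index[self.table["call"] == "DOWN"])


def size_factors(counts: pd.DataFrame, method: str = "ratio") -> pd.Series:
    """Median-of-ratios normalization factors (geometric-mean reference).

    ``method="ratio"`` uses genes with nonzero counts in every sample;
    ``method="poscounts"`` takes the n-th root of the product of positive
    counts as the reference, keeping sparse genes in the median — use it
    when few genes are everywhere-nonzero or when a large fraction of the
    everywhere-nonzero genes is differentially expressed.
    """
    arr = counts.to_numpy(dtype=float)
    if method == "ratio":
        all_nonzero = np.all(arr > 0, axis=1)
        if not np.any(all_nonzero):
            raise ValueError(
                "no gene has nonzero counts in every sample; median-of-ratios "
                "needs at least one (use method='poscounts')"
            )
        sub = arr[all_nonzero]
        log_geo_mean = np.log(sub).mean(axis=1)
        factors = np.exp(np.median(np.log(sub) - log_geo_mean[:, None], axis=0))
    elif method == "poscounts":
        any_pos = np.any(arr > 0, axis=1)
        sub = arr[any_pos]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), 0.0)
        log_geo_mean = logs.sum(axis=1) / sub.shape[1]
        ratios = sub / np.exp(log_geo_mean)[:, None]
        factors = np.median(ratios, axis=0)
        if np.any(factors <= 0):
            raise ValueError("poscounts size factors collapsed to zero; data too sparse")
    else:
        raise ValueError("method must be 'ratio' or 'poscounts'")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: Sequence[str],
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene method-of-moments dispersion pooled within conditions.

    alpha_g = (pooled within-group variance - mean) / mean^2 on normalized
    counts, floored, then shrunk toward a 1/mu mean-dispersion trend with
    the declared weight.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    for lvl in levels:
        if (groups == lvl).sum() < 2:
            raise ValueError(
                f"group {lvl!r} has fewer than 2 replicates; dispersion "
                "cannot be estimated"
            )
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    n_genes = norm.shape[0]
    overall_mean = norm.mean(axis=1)
    num = np.zeros(n_genes)
    mean_sq_terms = np.zeros(n_genes)
    for lvl in levels:
        cols = groups == lvl
        n_rep = int(cols.sum())
        m = norm[:, cols].mean(axis=1)
        v = norm[:, cols].var(axis=1, ddof=1)
        # within-group excess variance relative to the Poisson expectation;
        # the mu^2 denominator uses the unbiased m^2 - v/n estimator
        num += v - m
        mean_sq_terms += m**2 - v / n_rep
    # genes where the mu^2 estimate collapses carry no dispersion
    # information; they fall back to the trend below
    informative = mean_sq_terms > 0
    raw = np.full(n_genes, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw[informative] = num[informative] / mean_sq_terms[informative]
    raw = np.clip(raw, DISPERSION_FLOOR, DISPERSION_CAP)
    # trend: alpha(mu) = a0 + a1/mu fitted by least squares
    mu = np.maximum(overall_mean, 1e-8)
    fit_mask = informative & (overall_mean > 0)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, raw[fit_mask], rcond=None)
        trend = np.clip(coef[0] + coef[1] / mu, DISPERSION_FLOOR, DISPERSION_CAP)
    else:
        fallback = np.nanmedian(raw) if np.any(informative) else DISPERSION_FLOOR
        trend = np.full(n_genes, np.clip(fallback, DISPERSION_FLOOR, DISPERSION_CAP))
    alpha = np.where(
        informative, (1.0 - shrink_weight) * raw + shrink_weight * trend, trend
    )
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CAP)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _nb_exact_p(k_a: int, k_b: int, mu_a: float, mu_b: float, size_a: float, size_b: float) -> float:
    """Two-sided conditioned NB exact test.

    Conditions on the total k_a + k_b; sums the probabilities of all splits
    no more likely than the observed one.
    """
    total = k_a + k_b
    if total == 0:
        return 1.0
    ks = np.arange(total + 1)
    log_pa = sps.nbinom.logpmf(ks, size_a, size_a / (size_a + mu_a))
    log_pb = sps.nbinom.logpmf(total - ks, size_b, size_b / (size_b + mu_b))
    log_joint = log_pa + log_pb
    log_joint -= log_joint.max()
    joint = np.exp(log_joint)
    denom = joint.sum()
    obs = joint[k_a]
    # small relative slack so the observed split is always included
    p = joint[joint <= obs * (1 + 1e-12)].sum() / denom
    return float(min(1.0, p))


def nb_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    groups: Sequence[str],
    reference: Optional[str] = None,
    lfc_pseudo: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 fold-change and two-sided NB exact p-value.

    log2FC compares the non-reference (perturbed) group to the reference;
    the +0.5 pseudo-count enters the fold-change only, never the test.
    """
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    if reference is None:
        reference = levels[0]
    other = [lvl for lvl in levels if lvl != reference][0]
    cols_a = groups == reference
    cols_b = groups == other
    arr = counts.to_numpy(dtype=float)
    fac = factors.to_numpy()
    norm = arr / fac[None, :]
    mean_a = norm[:, cols_a].mean(axis=1)
    mean_b = norm[:, cols_b].mean(axis=1)
    log2fc = np.log2((mean_b + lfc_pseudo) / (mean_a + lfc_pseudo))
    base_mean = norm.mean(axis=1)
    n_a, n_b = int(cols_a.sum()), int(cols_b.sum())
    # exact test on the raw per-condition totals, conditioning on the raw
    # grand total; the null mean splits proportionally to each group's
    # size-factor sum, so unequal depths need no rounding
    k_a_arr = arr[:, cols_a].sum(axis=1).astype(np.int64)
    k_b_arr = arr[:, cols_b].sum(axis=1).astype(np.int64)
    s_a, s_b = float(fac[cols_a].sum()), float(fac[cols_b].sum())
    alphas = dispersions.to_numpy()
    p_values = np.ones(len(counts))
    for i in range(len(counts)):
        total = k_a_arr[i] + k_b_arr[i]
        if total == 0:
            continue
        q = total / (s_a + s_b)
        mu_a, mu_b = q * s_a, q * s_b
        # sum of n iid NB(mu, alpha) is NB(n*mu, alpha/n): size n/alpha
        size_a = n_a / max(alphas[i], DISPERSION_FLOOR)
        size_b = n_b / max(alphas[i], DISPERSION_FLOOR)
        p_values[i] = _nb_exact_p(int(k_a_arr[i]), int(k_b_arr[i]), mu_a, mu_b, size_a, size_b)
    return pd.DataFrame(
        {"baseMean": base_mean, "log2FC": log2fc, "p_value": p_values},
        index=counts.index,
    )


def classify_de(
    log2fc: float, p: float, fold_threshold: float = 2.0, p_threshold: float = 0.05
) -> str:
    """Strict-inequality call rule: UP/DOWN need |fold| > threshold AND p < cutoff."""
    if p < p_threshold and log2fc > np.log2(fold_threshold):
        return "UP"
    if p < p_threshold and log2fc < -np.log2(fold_threshold):
        return "DOWN"
    return "NONE"


def run_de(
    counts: pd.DataFrame,
    groups: Sequence[str],
    reference: Optional[str] = None,
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
    shrink_weight: float = 0.5,
    size_factor_method: str = "poscounts",
) -> DEResult:
    """Full stage: size factors -> dispersion -> exact test -> calls."""
    factors = size_factors(counts, method=size_factor_method)
    dispersions = estimate_dispersion(counts, factors, groups, shrink_weight)
    table = nb_test(counts, factors, dispersions, groups, reference=reference)
    table["q_value"] = adjust_bh(table["p_value"].to_numpy())
    table["call"] = [
        classify_de(l, p, fold_threshold, p_threshold)
        for l, p in zip(table["log2FC"], table["p_value"])
    ]
    table["call4"] = [
        classify_de(l, p, 4.0, p_threshold)
        for l, p in zip(table["log2FC"], table["p_value"])
    ]
    return DEResult(table=table)
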