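import itertools

import numpy as np
import pandas as pd
import pytest

from chromark.assoc import (
    ALL_CLASS_LABELS,
    box_stats,
    derepression_fraction,
    mann_whitney_u,
    mark_cooccurrence,
    stratified_expression,
)
from chromark.core import GenomicInterval
from chromark.diffexpr import DEResult
from chromark.promoters import PromoterMarkCalls, class_label
from chromark.simulate import MARK_K4, MARK_K27, MARK_UB


def enumeration_p(x, y):
    """Oracle: exact two-tailed p by enumerating all label assignments."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = x + y

    def u_of(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_of(x, y)
    us = []
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in combo]
        us.append(u_of(xs, ys))
    us = np.array(us)
    lower = (us <= u_obs + 1e-9).mean()
    upper = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


class TestMannWhitney:
    def test_spec_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2
        assert p > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 3), (3, 3), (4, 2), (5, 5), (7, 6), (7, 7)])
    def test_exact_path_equals_enumeration(self, rng, n, m):
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
            x, y = vals[:n], vals[n:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_approximation_close_to_exact_at_n12(self, rng):
        # n = m = 12 forces the normal path; compare to scipy's exact p
        from scipy.stats import mannwhitneyu as scipy_mwu

        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, 25.0))
            x, y = vals[:12], vals[12:]
            _, p = mann_whitney_u(x, y)
            p_exact = scipy_mwu(x, y, alternative="two-sided", method="exact").pvalue
            assert abs(p - p_exact) <= 0.01

    def test_ties_fall_back_to_approximation(self):
        u, p = mann_whitney_u([1, 1, 2], [1, 2, 2])
        assert 0 <= p <= 1


class TestBoxStats:
    def test_hand_example(self):
        stats = box_stats([1, 2, 3, 4, 5])
        assert stats == {
            "q25": 2.0, "median": 3.0, "q75": 4.0,
            "lower_whisker": 1.0, "upper_whisker": 5.0,
        }

    def test_constant_vector(self):
        stats = box_stats([7.0] * 5)
        assert all(v == 7.0 for v in stats.values())

    def test_outlier_beyond_fence_ignored(self):
        base = [1, 2, 3, 4, 5]
        stats = box_stats(base + [1000.0])
        iqr = stats["q75"] - stats["q25"]
        assert stats["upper_whisker"] <= stats["q75"] + 1.5 * iqr

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            box_stats([])


def _make_calls(rows):
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    table["label"] = [
        class_label(r[f"has_{MARK_UB}"], r[f"has_{MARK_K4}"], r[f"has_{MARK_K27}"])
        for _, r in table.iterrows()
    ]
    return PromoterMarkCalls(table=table)


def _row(ub=False, k4=False, k27=False):
    return {f"has_{MARK_UB}": ub, f"has_{MARK_K4}": k4, f"has_{MARK_K27}": k27}


def _de_result(gene_ids, calls):
    table = pd.DataFrame(
        {
            "baseMean": 10.0,
            "log2FC": [2.0 if c == "UP" else 0.0 for c in calls],
            "p_value": [0.01 if c == "UP" else 0.9 for c in calls],
            "q_value": [0.05 if c == "UP" else 0.95 for c in calls],
            "call": calls,
            "call4": ["NONE"] * len(calls),
        },
        index=gene_ids,
    )
    return DEResult(table=table)


class TestStratifiedExpression:
    def test_single_class_equals_direct_computation(self, rng):
        genes = [f"g{i}" for i in range(20)]
        calls = _make_calls({g: _row(ub=True, k4=True) for g in genes})
        r_ctrl = pd.Series(rng.random(20) * 10, index=genes)
        r_pert = pd.Series(rng.random(20) * 10, index=genes)
        de = _de_result(genes, ["UP"] * 5 + ["NONE"] * 15)
        report = stratified_expression(calls, r_ctrl, r_pert, de)
        row = report.table.loc["Ub+K4"]
        assert row["n_genes"] == 20
        assert row["fraction_up"] == pytest.approx(0.25)
        expected = box_stats(np.arcsinh(r_ctrl.to_numpy()))
        assert row["control_median"] == pytest.approx(expected["median"])

    def test_class_counts_partition_universe(self, rng):
        rows = {}
        for i in range(100):
            rows[f"g{i}"] = _row(
                ub=bool(rng.integers(2)), k4=bool(rng.integers(2)), k27=bool(rng.integers(2))
            )
        calls = _make_calls(rows)
        genes = list(rows)
        r = pd.Series(rng.random(100), index=genes)
        de = _de_result(genes, ["NONE"] * 100)
        report = stratified_expression(calls, r, r, de)
        assert report.table["n_genes"].sum() == 100
        assert set(report.table.index) == set(ALL_CLASS_LABELS)

    def test_empty_class_reported_with_zero_count(self, rng):
        genes = ["g1", "g2"]
        calls = _make_calls({g: _row(ub=True) for g in genes})
        r = pd.Series([1.0, 2.0], index=genes)
        de = _de_result(genes, ["NONE", "NONE"])
        report = stratified_expression(calls, r, r, de)
        assert report.table.loc["K4", "n_genes"] == 0
        assert np.isnan(report.table.loc["K4", "fraction_up"])


class TestDerepressionFraction:
    def test_no_up_calls(self):
        genes = [f"g{i}" for i in range(10)]
        calls = _make_calls({g: _row(ub=True, k27=True) for g in genes})
        de = _de_result(genes, ["NONE"] * 10)
        assert derepression_fraction(calls, de) == (0, 10, 0.0)

    def test_one_in_ten(self):
        genes = [f"g{i}" for i in range(10)]
        calls = _make_calls({g: _row(ub=True, k27=True) for g in genes})
        de = _de_result(genes, ["UP"] + ["NONE"] * 9)
        assert derepression_fraction(calls, de) == (1, 10, 0.1)

    def test_agrees_with_manual_recount_on_fixture(self, rng):
        rows, call_list, genes = {}, [], []
        for i in range(50):
            g = f"g{i}"
            genes.append(g)
            rows[g] = _row(
                ub=bool(rng.integers(2)), k4=bool(rng.integers(2)), k27=bool(rng.integers(2))
            )
            call_list.append(["UP", "DOWN", "NONE"][rng.integers(3)])
        calls = _make_calls(rows)
        de = _de_result(genes, call_list)
        n_up, n_class, frac = derepression_fraction(calls, de)
        manual = [
            g for g in genes
            if rows[g][f"has_{MARK_UB}"]
            and rows[g][f"has_{MARK_K27}"]
            and not rows[g][f"has_{MARK_K4}"]
        ]
        manual_up = sum(
            1 for g, c in zip(genes, call_list) if g in manual and c == "UP"
        )
        assert (n_up, n_class) == (manual_up, len(manual))

    def test_empty_class_warns(self):
        genes = ["g1"]
        calls = _make_calls({g: _row() for g in genes})
        de = _de_result(genes, ["NONE"])
        with pytest.warns(UserWarning):
            n_up, n_class, frac = derepression_fraction(calls, de)
        assert np.isnan(frac)


class TestMarkCooccurrence:
    def test_identity(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)]
        out = mark_cooccurrence(a, a)
        assert out["frac_a_overlapping_b"] == 1.0

    def test_disjoint(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 200, 300)]
        assert mark_cooccurrence(a, b)["frac_a_overlapping_b"] == 0.0

    def test_empty_warns_nan(self):
        with pytest.warns(UserWarning):
            out = mark_cooccurrence([], [GenomicInterval("chr1", 0, 10)])
        assert np.isnan(out["frac_a_overlapping_b"])

    def test_composite_union(self):
        b = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1000, 1100)]
        c = [GenomicInterval("chr1", 50, 150)]
        a = [GenomicInterval("chr1", 140, 160)]
        out = mark_cooccurrence(a, b, c)
        # composite = merge([0,100),[50,150)) = [0,150); A overlaps it
        assert out["frac_composite_with_a"] == 1.0

    def test_composite_intersection_mode(self):
        b = [GenomicInterval("chr1", 0, 100)]
        c = [GenomicInterval("chr1", 50, 150)]
        a = [GenomicInterval("chr1", 120, 130)]
        out_union = mark_cooccurrence(a, b, c, composite="union")
        out_inter = mark_cooccurrence(a, b, c, composite="intersection")
        # intersection composite is [50,100): A misses it; union is [0,150): A hits
        assert out_union["frac_composite_with_a"] == 1.0
        assert out_inter["frac_composite_with_a"] == 0.0

    def test_planted_cooccurrence_recovered(self):
        from chromark.core import fraction_regions_overlapping
        from chromark.simulate import SimulationConfig, plant_domains, simulate_annotation

        config = SimulationConfig(
            seed=30, n_genes=2000, n_chroms=4, chrom_length=11_000_000,
            class_proportions=(0, 0, 1, 0, 0), co_occurrence_frac=0.74,
        )
        sizes, genes, classes = simulate_annotation(config)
        domains, _ = plant_domains(genes, classes, config, sizes)
        out = mark_cooccurrence(domains[MARK_UB], domains[MARK_K27])
        assert abs(out["frac_a_overlapping_b"] - 0.74) <= 0.04
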