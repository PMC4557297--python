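import numpy as np
import pytest
from scipy import stats as sps

from chromark.core import ChromSizes, fraction_regions_overlapping
from chromark.simulate import (
    CLASS_NAMES,
    GENE_CLASSES,
    MARK_K4,
    MARK_K27,
    MARK_UB,
    SimulationConfig,
    load_truth,
    plant_domains,
    simulate_annotation,
    simulate_dataset,
    simulate_expression,
    simulate_tag_library,
    write_truth,
)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_proportions=(0.5, 0.5, 0.5, 0, 0))

    def test_depletion_factor_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(depletion_factor_ub=1.5)

    def test_positive_densities(self):
        with pytest.raises(ValueError):
            SimulationConfig(background_density=0)


class TestSimulateAnnotation:
    def test_determinism(self):
        config = SimulationConfig(seed=1, n_genes=50, chrom_length=1_000_000)
        a = simulate_annotation(config)
        b = simulate_annotation(config)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2] == b[2]

    def test_all_one_class(self):
        config = SimulationConfig(
            seed=2, n_genes=40, chrom_length=1_000_000,
            class_proportions=(1, 0, 0, 0, 0),
        )
        _, _, classes = simulate_annotation(config)
        assert set(classes.values()) == {"ACTIVE_K4"}

    def test_class_fractions_near_target(self):
        props = (0.3, 0.4, 0.1, 0.1, 0.1)
        config = SimulationConfig(
            seed=3, n_genes=2000, n_chroms=4, chrom_length=11_000_000,
            class_proportions=props,
        )
        _, genes, classes = simulate_annotation(config)
        for name, target in zip(CLASS_NAMES, props):
            frac = sum(1 for c in classes.values() if c == name) / len(classes)
            assert abs(frac - target) <= 0.03

    def test_genes_non_overlapping_and_long_enough(self):
        config = SimulationConfig(seed=4, n_genes=60, chrom_length=1_200_000)
        _, genes, _ = simulate_annotation(config)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
            assert g.span >= 600
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.start)
            for a, b in zip(glist, glist[1:]):
                assert a.end <= b.start

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack|genome"):
            simulate_annotation(
                SimulationConfig(seed=5, n_genes=1000, n_chroms=1, chrom_length=1_000_000)
            )


class TestPlantDomains:
    def _annotate(self, **kwargs):
        config = SimulationConfig(**kwargs)
        sizes, genes, classes = simulate_annotation(config)
        return config, sizes, genes, classes

    def test_unmarked_contributes_nothing(self):
        config, sizes, genes, classes = self._annotate(
            seed=6, n_genes=30, chrom_length=1_000_000,
            class_proportions=(0, 0, 0, 0, 1),
        )
        domains, truth = plant_domains(genes, classes, config, sizes)
        assert all(len(v) == 0 for v in domains.values())

    def test_cooccurrence_one_means_every_ub_has_k27(self):
        config, sizes, genes, classes = self._annotate(
            seed=7, n_genes=60, chrom_length=1_500_000,
            class_proportions=(0, 0, 1, 0, 0), co_occurrence_frac=1.0,
        )
        domains, _ = plant_domains(genes, classes, config, sizes)
        frac, _ = fraction_regions_overlapping(domains[MARK_UB], domains[MARK_K27])
        assert frac == 1.0

    def test_cooccurrence_recovery_within_binomial_error(self):
        config, sizes, genes, classes = self._annotate(
            seed=8, n_genes=2000, n_chroms=4, chrom_length=11_000_000,
            class_proportions=(0, 0, 1, 0, 0), co_occurrence_frac=0.74,
        )
        domains, _ = plant_domains(genes, classes, config, sizes)
        assert len(domains[MARK_UB]) >= 2000
        frac, _ = fraction_regions_overlapping(domains[MARK_UB], domains[MARK_K27])
        assert abs(frac - 0.74) <= 0.04

    def test_domains_within_bounds(self):
        config, sizes, genes, classes = self._annotate(seed=9, n_genes=50, chrom_length=1_000_000)
        domains, truth = plant_domains(genes, classes, config, sizes)
        for ivs in domains.values():
            for iv in ivs:
                sizes.validate_interval(iv)

    def test_truth_marks_match_domains(self):
        config, sizes, genes, classes = self._annotate(seed=10, n_genes=80, chrom_length=1_500_000)
        domains, truth = plant_domains(genes, classes, config, sizes)
        n_ub_genes = sum(1 for m in truth.gene_marks.values() if MARK_UB in m)
        assert n_ub_genes == len(domains[MARK_UB])
        n_k27_genes = sum(1 for m in truth.gene_marks.values() if MARK_K27 in m)
        assert n_k27_genes == len(domains[MARK_K27])


class TestSimulateTagLibrary:
    def test_null_chip_indistinguishable_from_input(self):
        config = SimulationConfig(
            seed=11, enrichment_fold=1.0, n_tags=10_000, n_chroms=1,
            chrom_length=2_000_000,
        )
        sizes = ChromSizes({"chr1": 2_000_000})
        chip, input_lib = simulate_tag_library([], config, sizes)
        stat = sps.ks_2samp(chip.positions["chr1"], input_lib.positions["chr1"])
        assert stat.pvalue > 0.01

    def test_determinism(self):
        config = SimulationConfig(seed=12, n_chroms=1, chrom_length=500_000)
        sizes = ChromSizes({"chr1": 500_000})
        a, _ = simulate_tag_library([], config, sizes, rng=config.spawn_rng("tags"))
        b, _ = simulate_tag_library([], config, sizes, rng=config.spawn_rng("tags"))
        assert np.array_equal(a.positions["chr1"], b.positions["chr1"])

    def test_in_domain_count_poisson_concentration(self):
        from chromark.core import GenomicInterval

        length = 2_000_000
        config = SimulationConfig(
            seed=13, enrichment_fold=8.0, background_density=2.5,
            n_chroms=1, chrom_length=length,
        )
        sizes = ChromSizes({"chr1": length})
        domain = GenomicInterval("chr1", 1_000_000, 1_010_000)
        chip, _ = simulate_tag_library([domain], config, sizes)
        pos = chip.positions["chr1"]
        observed = np.searchsorted(pos, domain.end) - np.searchsorted(pos, domain.start)
        expected = 2.5 * 8.0 * 10_000 / 1000
        assert abs(observed - expected) <= 3 * np.sqrt(expected)

    def test_exact_total_when_n_tags_given(self):
        config = SimulationConfig(seed=14, n_tags=12_345, n_chroms=1, chrom_length=500_000)
        sizes = ChromSizes({"chr1": 500_000})
        chip, input_lib = simulate_tag_library([], config, sizes)
        assert chip.total_tags == 12_345
        assert input_lib.total_tags == 12_345

    def test_depleted_condition_reduces_domain_tags(self):
        from chromark.core import GenomicInterval

        length = 2_000_000
        config = SimulationConfig(seed=15, n_chroms=1, chrom_length=length)
        sizes = ChromSizes({"chr1": length})
        domain = GenomicInterval("chr1", 500_000, 520_000)

        def in_domain(condition, factor):
            chip, _ = simulate_tag_library(
                [domain], config, sizes, condition=condition, depletion_factor=factor,
                rng=config.spawn_rng("tags"),
            )
            pos = chip.positions["chr1"]
            return np.searchsorted(pos, domain.end) - np.searchsorted(pos, domain.start)

        assert in_domain("depleted", 0.9) < 0.3 * in_domain("baseline", 0.0)

    def test_zero_intensity_raises(self):
        config = SimulationConfig(seed=16, n_chroms=1, chrom_length=500_000)
        with pytest.raises(ValueError):
            simulate_tag_library([], config, ChromSizes({}))


class TestSimulateExpression:
    def _genes(self, n=2000, seed=17, props=(0.2, 0.2, 0.2, 0.2, 0.2)):
        config = SimulationConfig(
            seed=seed, n_genes=n, n_chroms=4, chrom_length=11_000_000,
            class_proportions=props,
        )
        _, genes, classes = simulate_annotation(config)
        return config, genes, classes

    def test_null_ratio_centred_on_one(self):
        config, genes, classes = self._genes()
        lfc0 = {g.gene_id: 0.0 for g in genes}
        counts, _ = simulate_expression(genes, classes, config, gene_log2fc=lfc0)
        ctrl = counts.iloc[:, :3].mean(axis=1)
        dep = counts.iloc[:, 3:].mean(axis=1)
        expressed = ctrl > 5
        ratio = (dep[expressed] + 0.5) / (ctrl[expressed] + 0.5)
        assert 0.9 <= ratio.median() <= 1.1

    def test_poisson_limit(self):
        config, genes, classes = self._genes(props=(1.0, 0, 0, 0, 0))
        config2 = SimulationConfig(
            **{**config.__dict__, "nb_dispersion": 1e-6, "gene_mean_log2_sd": 0.0}
        )
        counts, _ = simulate_expression(genes, classes, config2)
        arr = counts.to_numpy(dtype=float)
        vmr = arr.var(axis=1, ddof=1) / arr.mean(axis=1)
        assert abs(np.median(vmr) - 1.0) < 0.2

    def test_determinism(self):
        config, genes, classes = self._genes(n=100, seed=18)
        a, _ = simulate_expression(genes, classes, config)
        b, _ = simulate_expression(genes, classes, config)
        assert a.equals(b)

    def test_planted_lfc_recorded(self):
        config, genes, classes = self._genes(n=200, seed=19)
        _, lfc = simulate_expression(genes, classes, config)
        for g in genes:
            expected = (
                config.perturbation_log2fc
                if GENE_CLASSES[classes[g.gene_id]].perturbation_log2fc > 0
                else 0.0
            )
            assert lfc[g.gene_id] == expected


class TestTruthRoundTrip:
    def test_write_load_identity(self, tmp_path, small_dataset):
        truth = small_dataset.truth
        write_truth(truth, tmp_path / "truth")
        loaded = load_truth(tmp_path / "truth")
        assert loaded.gene_classes == truth.gene_classes
        assert loaded.gene_marks == truth.gene_marks
        assert loaded.gene_log2fc == truth.gene_log2fc
        assert loaded.seed == truth.seed
        for mark, ivs in truth.domains.items():
            assert [(i.chrom, i.start, i.end) for i in loaded.domains[mark]] == [
                (i.chrom, i.start, i.end) for i in sorted(ivs, key=lambda x: (x.chrom, x.start))
            ]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_truth(tmp_path / "nonexistent")

    def test_class_row_count(self, tmp_path, small_dataset):
        write_truth(small_dataset.truth, tmp_path / "t")
        n_rows = sum(1 for _ in open(tmp_path / "t" / "gene_truth.tsv")) - 1
        assert n_rows == len(small_dataset.genes)


class TestDatasetDeterminism:
    def test_full_dataset_reproducible(self):
        config = SimulationConfig(seed=20, n_genes=40, chrom_length=1_000_000)
        a = simulate_dataset(config)
        b = simulate_dataset(config)
        assert a.counts.equals(b.counts)
        for mark in a.chip:
            for chrom in a.chip[mark].positions:
                assert np.array_equal(
                    a.chip[mark].positions[chrom], b.chip[mark].positions[chrom]
                )
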