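"""Classification rules and cohort landscape statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_fusion
from fusionscape.landscape import (
    classify_fusion,
    density_correlation,
    per_sample_counts,
    summarize_landscape,
    unique_pairs,
)
from fusionscape.model import (
    CohortTable,
    DataError,
    GeneAnnotation,
    GeneRecord,
    IgClass,
    SampleMeta,
)


class TestClassifyFusion:
    def test_ig_partner_sets_class(self, toy_annotation):
        f = make_fusion(gene5="IGHG1", gene3="NSD2")
        classify_fusion(f, toy_annotation)
        assert f.is_ig and f.ig_class is IgClass.IGH

    def test_alias_resolves_before_classification(self, toy_annotation):
        f = make_fusion(gene5="IGKC", gene3="MMSET")
        classify_fusion(f, toy_annotation)
        assert f.is_ig and f.ig_class is IgClass.IGK and not f.unresolved

    def test_read_through_candidates_on_chr19(self, toy_annotation):
        f = make_fusion(gene5="TPM4", gene3="ISYNA1")
        classify_fusion(f, toy_annotation)
        assert f.is_same_chr_lt10mb  # ~2 Mb apart

    def test_same_chromosome_but_far_apart_is_not_read_through(self, toy_annotation):
        f = make_fusion(gene5="TPM4", gene3="FARAWAY")  # ~24 Mb gap
        classify_fusion(f, toy_annotation)
        assert not f.is_same_chr_lt10mb

    def test_gap_distance_is_between_spans_not_starts(self, toy_annotation):
        # span gap just under 10 Mb although the starts are ~13 Mb apart
        f = make_fusion(gene5="NEAR_EDGE", gene3="FARAWAY")
        classify_fusion(f, toy_annotation)
        assert f.is_same_chr_lt10mb

    def test_different_chromosomes_never_read_through(self, toy_annotation):
        f = make_fusion(gene5="IGHG1", gene3="NSD2")
        classify_fusion(f, toy_annotation)
        assert not f.is_same_chr_lt10mb

    def test_unresolved_gene_defers_classification(self, toy_annotation):
        f = make_fusion(gene5="UNKNOWN_GENE", gene3="NSD2")
        classify_fusion(f, toy_annotation)
        assert f.unresolved


def _cohort(fusions, n_samples=4, population="patient"):
    meta = {
        f"S{i}": SampleMeta(sample_id=f"S{i}", population=population)
        for i in range(1, n_samples + 1)
    }
    return CohortTable(fusions, meta)


class TestUniquePairs:
    def test_distinct_sample_counts(self):
        fusions = [
            make_fusion(sample="S1", gene5="A", gene3="B"),
            make_fusion(sample="S2", gene5="A", gene3="B"),
            make_fusion(sample="S2", gene5="B", gene3="A"),
        ]
        counts = unique_pairs(_cohort(fusions))
        assert counts[("A", "B")] == 2
        assert counts[("B", "A")] == 1  # reciprocal orientation kept separate

    def test_all_distinct_pairs_means_no_recurrence(self):
        fusions = [
            make_fusion(sample="S1", gene5="A", gene3="B"),
            make_fusion(sample="S2", gene5="C", gene3="D"),
        ]
        counts = unique_pairs(_cohort(fusions))
        assert (counts >= 2).sum() == 0

    def test_filtered_out_fusions_do_not_count(self):
        f = make_fusion(sample="S1", gene5="A", gene3="B")
        f.passed_support_filter = False
        assert len(unique_pairs(_cohort([f]))) == 0


class TestSummarize:
    def test_single_ig_fusion_cohort(self, toy_annotation):
        f = make_fusion(sample="S1", gene5="IGHG1", gene3="NSD2")
        classify_fusion(f, toy_annotation)
        s = summarize_landscape(_cohort([f], n_samples=1))
        assert s.n_unique_pairs == 1
        assert s.pct_ig_of_unique == 100.0
        assert s.pct_samples_with["all"]["Ig"] == 100.0
        assert s.pct_samples_with["all"]["IGH"] == 100.0

    def test_decomposition_covers_unique_pairs(self, tiny_cohort):
        for pop in ("patient", "cell_line"):
            s = summarize_landscape(tiny_cohort, pop)
            assert (
                s.pct_ig_of_unique
                + s.pct_recurrent_non_ig_of_unique
                + s.pct_other_of_unique
            ) == pytest.approx(100.0)

    def test_per_sample_counts_sum_to_total(self, tiny_cohort):
        s = summarize_landscape(tiny_cohort, "patient")
        assert s.per_sample_counts.sum() == s.n_fusions_total
        assert len(s.per_sample_counts) == s.n_samples

    def test_empty_cohort_is_all_zero(self):
        s = summarize_landscape(_cohort([]))
        assert s.n_fusions_total == 0 and s.n_unique_pairs == 0
        assert s.pct_ig_of_unique == 0.0

    def test_generator_ig_share_recovered(self, tiny_sim, tiny_cohort):
        # 30-patient cohort: expect the configured unique-pair Ig share
        # within a generous binomial band
        s = summarize_landscape(tiny_cohort, "patient")
        target = 100 * tiny_sim.config.target_ig_share_unique
        se = 100 * np.sqrt(0.36 * 0.64 / s.n_unique_pairs)
        assert abs(s.pct_ig_of_unique - target) < 4 * se


def _toy_density_setup():
    """3 chromosomes whose fusion counts are exactly proportional to density."""
    genes = []
    layout = {"c1": (10e6, 2), "c2": (10e6, 4), "c3": (10e6, 6)}
    for chrom, (length, n) in layout.items():
        for i in range(n):
            start = int(1e6 * (i + 1))
            genes.append(GeneRecord(f"{chrom}G{i}", chrom, start, start + 1000, "+"))
    ann = GeneAnnotation(genes, chrom_lengths={c: l for c, (l, _) in layout.items()})
    # intra-chromosomal fusions: 1 on c1, 2 on c2, 3 on c3
    fusions = []
    for chrom, k in (("c1", 1), ("c2", 2), ("c3", 3)):
        for i in range(k):
            fusions.append(
                make_fusion(
                    sample="S1",
                    gene5=f"{chrom}G{2 * i}",
                    gene3=f"{chrom}G{2 * i + 1}",
                    chrom5=chrom,
                    chrom3=chrom,
                )
            )
    return ann, _cohort(fusions, n_samples=1)


class TestDensityCorrelation:
    def test_exact_collinearity_gives_r_of_one(self):
        ann, cohort = _toy_density_setup()
        density, r = density_correlation(cohort, ann)
        assert r == pytest.approx(1.0)

    def test_intra_chromosomal_fusions_counted_twice(self):
        ann, cohort = _toy_density_setup()
        density, _ = density_correlation(cohort, ann)
        assert density["fusion_gene_count"].sum() == 2 * len(cohort.retained())
        assert density.loc["c3", "fusion_gene_count"] == 6

    def test_permuted_counts_center_at_zero(self, tiny_sim, tiny_cohort, rng):
        density, _ = density_correlation(tiny_cohort, tiny_sim.annotation)
        x = density["genes_per_mb"].to_numpy()
        y = density["fusion_gene_count"].to_numpy(dtype=float)
        rs = []
        for _ in range(500):
            rs.append(np.corrcoef(x, rng.permutation(y))[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_excluding_ig_hotspot_chromosomes_raises_r(self, tiny_sim, tiny_cohort):
        # the generator plants Ig hotspots on chr2/chr14/chr22, which inflate
        # those chromosomes above the density trend
        _, r_all = density_correlation(tiny_cohort, tiny_sim.annotation)
        _, r_excl = density_correlation(
            tiny_cohort, tiny_sim.annotation, exclude={"chr2", "chr14", "chr22"}
        )
        assert r_excl >= r_all

    def test_too_few_chromosomes_is_an_error(self):
        ann, cohort = _toy_density_setup()
        with pytest.raises(DataError):
            density_correlation(cohort, ann, exclude={"c1"})


class TestPerSampleCounts:
    def test_zero_for_fusion_free_samples(self):
        fusions = [make_fusion(sample="S1", gene5="A", gene3="B")]
        out = per_sample_counts(_cohort(fusions, n_samples=3))
        assert out["counts"]["S2"] == 0 and out["counts"]["S1"] == 1

    def test_threshold_counting_and_grouping(self, tiny_cohort):
        out = per_sample_counts(
            tiny_cohort, groupby="ploidy_group", population="patient", threshold=15
        )
        assert out["n_above_threshold"] == int((out["counts"] > 15).sum())
        assert set(out["groups"].index) <= {"high_hyperdiploid", "other", "unknown"}

    def test_unknown_grouping_field_raises(self, tiny_cohort):
        with pytest.raises(DataError):
            per_sample_counts(tiny_cohort, groupby="not_a_field")
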