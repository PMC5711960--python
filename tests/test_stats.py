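"""Permutation tests, expression comparisons and burden-covariate association."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_fusion
from fusionscape.model import CohortTable, DataError, SampleMeta
from fusionscape.stats import (
    burden_vs_covariate,
    fused_expression_tests,
    ks_permutation_test,
    mean_diff_permutation_test,
)


class TestKsPermutation:
    def test_identical_groups_give_large_p(self):
        x = [1, 2, 3, 4, 5]
        res = ks_permutation_test(x, x, n_perm=999, seed=0)
        assert res.observed == 0.0
        assert res.p_value > 0.5

    def test_fully_separated_groups_reach_minimal_p(self):
        res = ks_permutation_test([0.0] * 10, [10.0] * 10, n_perm=999, seed=0)
        assert res.observed == 1.0
        # minimum attainable with the add-one estimator is 1/(n_perm+1); a
        # few permutations reproduce the all-zeros/all-tens split by chance
        assert res.p_value < 0.01
        assert res.p_value >= 1 / 1000

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        r1 = ks_permutation_test(x, y, n_perm=999, seed=42)
        r2 = ks_permutation_test(x, y, n_perm=999, seed=42)
        assert r1 == r2

    def test_agrees_with_exhaustive_enumeration_on_small_groups(self):
        x = [0.1, 0.7, 1.3, 2.9]
        y = [0.5, 1.1, 4.2, 5.0]
        pooled = np.array(x + y)

        def ks(a, b):
            grid = np.sort(np.unique(pooled))
            fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
            fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
            return np.abs(fa - fb).max()

        observed = ks(x, y)
        stats = []
        for idx in itertools.combinations(range(8), 4):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(8) if i not in idx]]
            stats.append(ks(a, b))
        p_exact = np.mean(np.array(stats) >= observed - 1e-12)
        res = ks_permutation_test(x, y, n_perm=19_999, seed=1)
        assert res.observed == pytest.approx(observed)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_empty_group_raises(self):
        with pytest.raises(DataError):
            ks_permutation_test([], [1.0], n_perm=99)

    def test_handles_heavily_tied_counts(self):
        # fusion burdens are small integers: ties everywhere
        x = [0, 0, 1, 1, 2, 2, 3]
        y = [0, 1, 1, 2, 2, 3, 3, 4]
        res = ks_permutation_test(x, y, n_perm=999, seed=3)
        assert 0 < res.p_value <= 1


class TestMeanDiffPermutation:
    def test_identical_groups_give_large_p(self):
        x = [2.0, 2.0, 2.0]
        res = mean_diff_permutation_test(x, x, n_perm=999, seed=0)
        assert res.p_value == 1.0

    def test_detects_planted_group_contrast(self, rng):
        # burden-style contrast: means 8.3 vs 3.8
        x = rng.poisson(8.3, size=60)
        y = rng.poisson(3.8, size=70)
        res = mean_diff_permutation_test(x, y, n_perm=1999, seed=5)
        assert res.observed == pytest.approx(abs(x.mean() - y.mean()))
        assert res.p_value < 0.01

    def test_reproducible_under_fixed_seed(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert mean_diff_permutation_test(
            x, y, n_perm=499, seed=9
        ) == mean_diff_permutation_test(x, y, n_perm=499, seed=9)


def _expression_cohort(rng, n_samples=60, shift_gene=None, shift=0.0, n_fused=12):
    meta = {
        f"S{i}": SampleMeta(sample_id=f"S{i}", population="patient")
        for i in range(n_samples)
    }
    genes = [f"G{j}" for j in range(8)]
    expr = pd.DataFrame(
        rng.normal(6, 1, size=(len(genes), n_samples)),
        index=genes,
        columns=list(meta),
    )
    fusions = []
    for j, gene in enumerate(genes):
        fused_samples = [f"S{i}" for i in range(j, j + n_fused)]
        for s in fused_samples:
            fusions.append(make_fusion(sample=s, gene5=gene, gene3=f"P{j}"))
        if gene == shift_gene:
            expr.loc[gene, fused_samples] += shift
    return CohortTable(fusions, meta), expr, genes


class TestFusedExpression:
    def test_planted_shift_is_flagged_significant(self, rng):
        cohort, expr, genes = _expression_cohort(rng, shift_gene="G3", shift=2.0)
        results = fused_expression_tests(cohort, expr, genes=genes)
        by_gene = {r.gene: r for r in results}
        assert by_gene["G3"].significant
        assert by_gene["G3"].mean_fused > by_gene["G3"].mean_unfused
        assert all(r.p_adjusted >= r.p_raw - 1e-12 for r in results if r.testable)

    def test_null_false_positive_rate_is_near_alpha(self, rng):
        n_sig = 0
        n_tests = 0
        for _ in range(40):
            cohort, expr, genes = _expression_cohort(rng)
            results = fused_expression_tests(cohort, expr, genes=genes, alpha=0.05)
            n_sig += sum(r.significant for r in results)
            n_tests += sum(r.testable for r in results)
        # BH controls FDR at alpha; under the global null that bounds the
        # per-test flag rate
        assert n_sig / n_tests < 0.05 + 0.02

    def test_single_gene_adjustment_is_identity(self, rng):
        cohort, expr, genes = _expression_cohort(rng)
        (res,) = fused_expression_tests(cohort, expr, genes=["G0"])
        assert res.p_adjusted == pytest.approx(res.p_raw)

    def test_gene_with_too_few_fused_samples_is_untestable(self, rng):
        cohort, expr, genes = _expression_cohort(rng, n_fused=1)
        results = fused_expression_tests(cohort, expr, genes=genes)
        assert all(not r.testable for r in results)
        assert all(np.isnan(r.p_adjusted) for r in results)

    def test_default_gene_set_is_most_recurrent_partners(self, tiny_sim, tiny_cohort):
        results = fused_expression_tests(
            tiny_cohort, tiny_sim.expression, n_genes=10
        )
        assert len(results) == 10

    def test_planted_overexpression_recovered_from_simulation(self, tiny_sim, tiny_cohort):
        results = fused_expression_tests(tiny_cohort, tiny_sim.expression, n_genes=10)
        testable = [r for r in results if r.testable]
        # fused genes carry a +2 log-unit shift in the generator
        assert sum(r.significant for r in testable) >= len(testable) * 0.5


class TestBurdenVsCovariate:
    def test_perfect_monotone_association(self):
        counts = [1, 2, 3, 4, 5, 6]
        cov = [10, 20, 30, 40, 50, 60]
        res = burden_vs_covariate(counts, cov, n_perm=999, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_independent_covariate_gives_near_zero_rho(self, rng):
        counts = rng.poisson(5, size=100)
        cov = rng.normal(size=100)
        res = burden_vs_covariate(counts, cov, n_perm=999, seed=0)
        assert abs(res.observed) < 0.3
        assert res.p_value > 0.01

    def test_generator_age_effect_recovered(self, tiny_cohort):
        from fusionscape.landscape import per_sample_counts

        counts = per_sample_counts(tiny_cohort, population="patient")["counts"]
        ages = [tiny_cohort.meta[s].age for s in counts.index]
        res = burden_vs_covariate(counts.to_numpy(), np.array(ages, dtype=float),
                                  n_perm=1999, seed=2)
        assert res.observed > 0

    def test_constant_covariate_raises(self):
        with pytest.raises(DataError):
            burden_vs_covariate([1, 2, 3, 4], [5, 5, 5, 5], n_perm=99)
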