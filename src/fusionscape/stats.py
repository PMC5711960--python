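"""Permutation tests and fused-vs-unfused expression comparisons.

All empirical p-values use the add-one estimator
``p = (1 + #{permuted stat >= observed}) / (1 + n_perm)``, which is never
zero and is exactly reproducible under a fixed seed. Randomness always comes
from an explicitly passed seed or ``numpy.random.Generator``; there is no
global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CohortTable, DataError

__all__ = [
    "PermutationResult",
    "ks_permutation_test",
    "mean_diff_permutation_test",
    "ExpressionTestResult",
    "fused_expression_tests",
    "burden_vs_covariate",
]

DEFAULT_KS_PERMS = 99_999
DEFAULT_MEANDIFF_PERMS = 9_999


@dataclass(frozen=True)
class PermutationResult:
    statistic_name: str
    observed: float
    n_permutations: int
    p_value: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        assert 0 < self.p_value <= 1


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _pooled(x, y) -> tuple[np.ndarray, int, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    return np.concatenate([x, y]), x.size, y.size


def _ks_rows(Z: np.ndarray, m: int, n: int, boundary: np.ndarray) -> np.ndarray:
    """Two-sample KS statistic per row of a label matrix.

    ``Z`` holds group-1 indicators aligned to the pooled *sorted* values;
    ``boundary`` marks the last index of each distinct pooled value, so ties
    are handled as in the classical statistic (ECDFs compared only at
    attained values).
    """
    cum1 = np.cumsum(Z, axis=1)[:, boundary] / m
    ranks = (np.flatnonzero(boundary) if boundary.dtype == bool else boundary) + 1
    cum2 = (ranks[None, :] - cum1 * m) / n
    return np.abs(cum1 - cum2).max(axis=1)


def _perm_label_batches(rng, base: np.ndarray, n_perm: int, batch: int):
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        yield rng.permuted(np.tile(base, (b, 1)), axis=1)
        done += b


def ks_permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = DEFAULT_KS_PERMS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    batch: int = 1024,
) -> PermutationResult:
    """Permutation test of the two-sample Kolmogorov-Smirnov statistic.

    Group labels are permuted under the null hypothesis of no difference in
    distribution; the p-value is the add-one tail share of permuted KS
    statistics at least as large as the observed one.
    """
    v, m, n = _pooled(x, y)
    order = np.argsort(v, kind="stable")
    v_sorted = v[order]
    boundary = np.flatnonzero(
        np.r_[v_sorted[1:] != v_sorted[:-1], True]
    )
    labels = np.zeros(m + n, dtype=np.int8)
    labels[:m] = 1
    labels_sorted = labels[order]
    observed = float(_ks_rows(labels_sorted[None, :], m, n, boundary)[0])
    generator = _as_rng(seed, rng)
    count = 0
    for Z in _perm_label_batches(generator, labels_sorted, n_perm, batch):
        count += int((_ks_rows(Z, m, n, boundary) >= observed - 1e-12).sum())
    return PermutationResult(
        statistic_name="KS",
        observed=observed,
        n_permutations=n_perm,
        p_value=(1 + count) / (1 + n_perm),
        n_x=m,
        n_y=n,
    )


def mean_diff_permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = DEFAULT_MEANDIFF_PERMS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    batch: int = 2048,
) -> PermutationResult:
    """Two-sided permutation test of the absolute difference in group means.

    Used for subgroup burden contrasts: Ig-fusion vs non-Ig-fusion patients
    (conditional on at least one fusion), FISH-translocated vs not, and
    high-hyperdiploid vs others.
    """
    v, m, n = _pooled(x, y)
    total = v.sum()
    labels = np.zeros(m + n, dtype=np.int8)
    labels[:m] = 1
    observed = abs(v[:m].mean() - v[m:].mean())
    generator = _as_rng(seed, rng)
    count = 0
    for Z in _perm_label_batches(generator, labels, n_perm, batch):
        s1 = Z @ v
        diff = np.abs(s1 / m - (total - s1) / n)
        count += int((diff >= observed - 1e-12).sum())
    return PermutationResult(
        statistic_name="mean_difference",
        observed=float(observed),
        n_permutations=n_perm,
        p_value=(1 + count) / (1 + n_perm),
        n_x=m,
        n_y=n,
    )


@dataclass
class ExpressionTestResult:
    gene: str
    n_fused: int
    n_unfused: int
    mean_fused: float
    mean_unfused: float
    t_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    testable: bool = True


def fused_expression_tests(
    cohort: CohortTable,
    expression: pd.DataFrame,
    genes: Sequence[str] | None = None,
    alpha: float = 0.01,
    method: str = "fdr_bh",
    population: str = "patient",
    n_genes: int = 36,
    equal_var: bool = True,
) -> list[ExpressionTestResult]:
    """Two-sided t-tests of log expression, fused vs unfused samples per gene.

    ``genes`` defaults to the ``n_genes`` most recurrent partner genes
    (ranked by the number of samples carrying a fusion of the gene). A gene
    with fewer than two fused or two unfused samples is flagged untestable
    and excluded from the multiple-testing adjustment (Benjamini-Hochberg by
    default; any ``statsmodels.stats.multitest`` method name works).
    """
    from statsmodels.stats.multitest import multipletests

    samples = [s for s in cohort.samples(population) if s in expression.columns]
    if not samples:
        raise DataError("no cohort samples found in the expression matrix")
    fused_by_gene: dict[str, set] = {}
    for f in cohort.retained(population):
        for gene in (f.gene5, f.gene3):
            fused_by_gene.setdefault(gene, set()).add(f.sample_id)
    if genes is None:
        ranked = sorted(
            fused_by_gene, key=lambda g: (-len(fused_by_gene[g]), g)
        )
        genes = [g for g in ranked if g in expression.index][:n_genes]
    results: list[ExpressionTestResult] = []
    for gene in genes:
        if gene not in expression.index:
            raise DataError(f"gene {gene!r} absent from the expression matrix")
        fused = sorted(fused_by_gene.get(gene, set()) & set(samples))
        unfused = [s for s in samples if s not in fused_by_gene.get(gene, set())]
        xf = expression.loc[gene, fused].to_numpy(dtype=float)
        xu = expression.loc[gene, unfused].to_numpy(dtype=float)
        testable = len(xf) >= 2 and len(xu) >= 2
        if testable:
            t, p = sps.ttest_ind(xf, xu, equal_var=equal_var)
        else:
            t, p = np.nan, np.nan
        results.append(
            ExpressionTestResult(
                gene=gene,
                n_fused=len(xf),
                n_unfused=len(xu),
                mean_fused=float(xf.mean()) if len(xf) else np.nan,
                mean_unfused=float(xu.mean()) if len(xu) else np.nan,
                t_statistic=float(t),
                p_raw=float(p),
                p_adjusted=np.nan,
                significant=False,
                testable=testable,
            )
        )
    testables = [r for r in results if r.testable]
    if testables:
        _, p_adj, _, _ = multipletests(
            [r.p_raw for r in testables], alpha=alpha, method=method
        )
        for r, p in zip(testables, p_adj):
            r.p_adjusted = float(p)
            r.significant = bool(p < alpha)
    return results


def expression_results_frame(results: Iterable[ExpressionTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("gene")


def burden_vs_covariate(
    counts: Sequence[float],
    covariate: Sequence[float],
    n_perm: int = DEFAULT_MEANDIFF_PERMS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    batch: int = 2048,
) -> PermutationResult:
    """Spearman correlation of per-sample fusion burden with a covariate.

    Two-sided permutation p-value on |rho| (the covariate is permuted
    against the counts). Missing covariate values are dropped pairwise;
    a constant covariate or fewer than 3 complete pairs is an error.
    """
    c = np.asarray(counts, dtype=float)
    z = np.asarray(covariate, dtype=float)
    keep = ~(np.isnan(c) | np.isnan(z))
    c, z = c[keep], z[keep]
    if c.size < 3:
        raise DataError("need at least 3 samples with covariate values")
    if np.ptp(z) == 0 or np.ptp(c) == 0:
        raise DataError("constant covariate or counts: correlation undefined")
    rc = sps.rankdata(c)
    rz = sps.rankdata(z)
    rc_c = rc - rc.mean()
    rz_c = rz - rz.mean()
    denom = np.sqrt((rc_c**2).sum() * (rz_c**2).sum())
    observed = float((rc_c * rz_c).sum() / denom)
    generator = _as_rng(seed, rng)
    count = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = generator.permuted(np.tile(rz_c, (b, 1)), axis=1)
        rho = perm @ rc_c / denom
        count += int((np.abs(rho) >= abs(observed) - 1e-12).sum())
        done += b
    return PermutationResult(
        statistic_name="spearman_rho",
        observed=observed,
        n_permutations=n_perm,
        p_value=(1 + count) / (1 + n_perm),
        n_x=c.size,
        n_y=c.size,
    )
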