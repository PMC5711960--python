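"""Cohort landscape statistics: classification, unique/recurrent fusions,
per-sample burden, and the chromosome gene-density correlation.

Definitions used throughout:

* unique fusion — a distinct ordered (5' gene, 3' gene) pair;
* recurrent fusion — a unique fusion observed in at least two samples of the
  same population (patients and cell lines are counted separately);
* Ig fusion — one partner lies in the immunoglobulin heavy (IGH), kappa
  (IGK) or lambda (IGL) locus;
* read-through candidate — partners on the same chromosome with gene spans
  separated by less than 10 Mb (gap distance; 0 if the spans overlap).

The landscape decomposition of unique pairs is: Ig fusions, recurrent
non-Ig fusions, and the rest ("others"), which together cover 100% of unique
pairs; "recurrent" overlaps Ig by construction and is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CohortTable,
    ConsensusFusion,
    DataError,
    GeneAnnotation,
    IgClass,
)

__all__ = [
    "READTHROUGH_MAX_DISTANCE",
    "classify_fusion",
    "classify_cohort",
    "unique_pairs",
    "annotate_recurrence",
    "LandscapeSummary",
    "summarize_landscape",
    "density_correlation",
    "per_sample_counts",
]

#: Maximum gap between gene spans for the read-through / in-situ class (bp).
READTHROUGH_MAX_DISTANCE = 10_000_000


def classify_fusion(
    fusion: ConsensusFusion, annotation: GeneAnnotation
) -> ConsensusFusion:
    """Set Ig and same-chromosome flags on one fusion (in place).

    If either partner cannot be resolved in the annotation the fusion is
    flagged ``unresolved`` and classification is deferred.
    """
    g5 = annotation.resolve(fusion.gene5)
    g3 = annotation.resolve(fusion.gene3)
    if g5 is None or g3 is None:
        fusion.unresolved = True
        return fusion
    fusion.unresolved = False
    if g5.is_ig:
        fusion.is_ig, fusion.ig_class = True, g5.ig_class
    elif g3.is_ig:
        fusion.is_ig, fusion.ig_class = True, g3.ig_class
    else:
        fusion.is_ig, fusion.ig_class = False, IgClass.NONE
    if g5.chrom == g3.chrom:
        gap = max(0, max(g5.start, g3.start) - min(g5.end, g3.end))
        fusion.is_same_chr_lt10mb = gap < READTHROUGH_MAX_DISTANCE
    else:
        fusion.is_same_chr_lt10mb = False
    return fusion


def classify_cohort(cohort: CohortTable, annotation: GeneAnnotation) -> CohortTable:
    """Classify every fusion and mark recurrence within each population."""
    for f in cohort.fusions:
        classify_fusion(f, annotation)
    annotate_recurrence(cohort)
    return cohort


def unique_pairs(cohort: CohortTable, population: str | None = None) -> pd.Series:
    """Distinct-sample count per ordered gene pair among retained fusions.

    A pair is recurrent within the population iff its count is >= 2.
    """
    counts: dict[tuple[str, str], set] = {}
    for f in cohort.retained(population):
        counts.setdefault(f.pair, set()).add(f.sample_id)
    if not counts:
        return pd.Series(dtype=int)
    idx = pd.MultiIndex.from_tuples(list(counts), names=["gene5", "gene3"])
    return pd.Series([len(v) for v in counts.values()], index=idx, dtype=int)


def annotate_recurrence(cohort: CohortTable) -> None:
    populations = {m.population for m in cohort.meta.values()}
    for pop in populations:
        pair_counts = unique_pairs(cohort, pop)
        recurrent = (
            set(pair_counts.index[pair_counts >= 2]) if len(pair_counts) else set()
        )
        for f in cohort.retained(pop):
            f.is_recurrent = f.pair in recurrent


@dataclass
class LandscapeSummary:
    """Cohort landscape numbers for one population.

    Percentages of unique pairs follow the Ig / recurrent / recurrent-non-Ig
    / others decomposition; ``pct_other_same_chr`` is the share of "others"
    whose partners are on the same chromosome less than 10 Mb apart.
    ``pct_samples_with`` holds the share of samples carrying at least one
    Ig / IGH / IGK / IGL fusion, overall and stratified by light-chain
    phenotype when metadata provides it. The Ig class split (IGH/IGK/IGL) is
    reported both over unique Ig pairs and over all Ig fusion events, since
    either denominator is meaningful.
    """

    population: str
    n_samples: int = 0
    n_fusions_total: int = 0
    n_unique_pairs: int = 0
    pct_ig_of_unique: float = 0.0
    pct_recurrent_of_unique: float = 0.0
    pct_recurrent_non_ig_of_unique: float = 0.0
    pct_other_of_unique: float = 0.0
    pct_other_same_chr: float = 0.0
    pct_samples_with: dict = field(default_factory=dict)
    ig_class_split_unique: dict = field(default_factory=dict)
    ig_class_split_events: dict = field(default_factory=dict)
    per_sample_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    per_gene_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "population",
                "n_samples",
                "n_fusions_total",
                "n_unique_pairs",
                "pct_ig_of_unique",
                "pct_recurrent_of_unique",
                "pct_recurrent_non_ig_of_unique",
                "pct_other_of_unique",
                "pct_other_same_chr",
            )
        }
        d["pct_samples_with"] = self.pct_samples_with
        d["ig_class_split_unique"] = self.ig_class_split_unique
        d["ig_class_split_events"] = self.ig_class_split_events
        return d


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else 0.0


def _sample_shares(
    fusions: Sequence[ConsensusFusion], sample_ids: Sequence[str]
) -> dict:
    has: dict[str, set] = {"Ig": set(), "IGH": set(), "IGK": set(), "IGL": set()}
    for f in fusions:
        if f.is_ig:
            has["Ig"].add(f.sample_id)
            has[f.ig_class.value].add(f.sample_id)
    n = len(sample_ids)
    ids = set(sample_ids)
    return {k: _pct(len(v & ids), n) for k, v in has.items()}


def summarize_landscape(
    cohort: CohortTable, population: str = "patient"
) -> LandscapeSummary:
    """Compute the landscape summary for one population.

    Requires the cohort to be classified (:func:`classify_cohort`). An empty
    cohort yields an all-zero summary.
    """
    annotate_recurrence(cohort)
    samples = cohort.samples(population)
    retained = cohort.retained(population)
    summary = LandscapeSummary(population=population, n_samples=len(samples))
    summary.n_fusions_total = len(retained)
    pair_counts = unique_pairs(cohort, population)
    summary.n_unique_pairs = len(pair_counts)
    if len(pair_counts) == 0:
        return summary

    # one representative fusion per pair for pair-level flags
    rep: dict[tuple[str, str], ConsensusFusion] = {}
    for f in retained:
        rep.setdefault(f.pair, f)
    pairs = list(pair_counts.index)
    is_ig = np.array([rep[p].is_ig for p in pairs])
    is_rec = pair_counts.values >= 2
    same_chr = np.array([rep[p].is_same_chr_lt10mb for p in pairs])
    n_unique = len(pairs)
    others = ~is_ig & ~is_rec
    summary.pct_ig_of_unique = _pct(is_ig.sum(), n_unique)
    summary.pct_recurrent_of_unique = _pct(is_rec.sum(), n_unique)
    summary.pct_recurrent_non_ig_of_unique = _pct((is_rec & ~is_ig).sum(), n_unique)
    summary.pct_other_of_unique = _pct(others.sum(), n_unique)
    summary.pct_other_same_chr = _pct((others & same_chr).sum(), others.sum())

    shares = {"all": _sample_shares(retained, samples)}
    by_lc: dict[str, list[str]] = {}
    for s in samples:
        lc = cohort.meta[s].light_chain
        if lc in ("kappa", "lambda"):
            by_lc.setdefault(lc, []).append(s)
    for lc, ids in sorted(by_lc.items()):
        shares[lc] = _sample_shares(retained, ids)
    summary.pct_samples_with = shares

    ig_pairs = [p for p, flag in zip(pairs, is_ig) if flag]
    if ig_pairs:
        cls_unique = pd.Series([rep[p].ig_class.value for p in ig_pairs])
        summary.ig_class_split_unique = {
            c: _pct((cls_unique == c).sum(), len(ig_pairs)) for c in ("IGH", "IGK", "IGL")
        }
        ig_events = [f for f in retained if f.is_ig]
        cls_events = pd.Series([f.ig_class.value for f in ig_events])
        summary.ig_class_split_events = {
            c: _pct((cls_events == c).sum(), len(ig_events))
            for c in ("IGH", "IGK", "IGL")
        }

    counts = pd.Series(0, index=samples, dtype=int)
    for f in retained:
        counts[f.sample_id] += 1
    summary.per_sample_counts = counts

    gene_rows: dict[str, dict] = {}
    for f in retained:
        for gene, partner in ((f.gene5, f.gene3), (f.gene3, f.gene5)):
            row = gene_rows.setdefault(
                gene, {"n_fusions": 0, "partners": set(), "samples": set()}
            )
            row["n_fusions"] += 1
            row["partners"].add(partner)
            row["samples"].add(f.sample_id)
    summary.per_gene_counts = pd.DataFrame(
        {
            "n_fusions": {g: r["n_fusions"] for g, r in gene_rows.items()},
            "n_partners": {g: len(r["partners"]) for g, r in gene_rows.items()},
            "n_samples": {g: len(r["samples"]) for g, r in gene_rows.items()},
        }
    ).sort_values(["n_samples", "n_fusions"], ascending=False)
    return summary


def density_correlation(
    cohort: CohortTable,
    annotation: GeneAnnotation,
    exclude: Iterable[str] = (),
    population: str | None = None,
) -> tuple[pd.DataFrame, float]:
    """Correlate per-chromosome fusion-gene counts with gene density.

    Each fusion contributes its two partner genes' chromosomes, so an
    intra-chromosomal fusion counts twice on its chromosome and the counts
    sum to twice the number of fusions. Pearson r is computed over the
    chromosomes not in ``exclude``; fewer than 3 remaining chromosomes is an
    error.
    """
    chroms = annotation.chromosomes()
    density = pd.DataFrame(
        {
            "length_mb": pd.Series(annotation.chrom_lengths, dtype=float) / 1e6,
            "n_genes": annotation.genes_per_chromosome(),
        },
        index=chroms,
    )
    density["genes_per_mb"] = density["n_genes"] / density["length_mb"]
    fusion_gene_count = pd.Series(0, index=chroms, dtype=int)
    for f in cohort.retained(population):
        for gene in (f.gene5, f.gene3):
            rec = annotation.resolve(gene)
            if rec is not None:
                fusion_gene_count[rec.chrom] += 1
    density["fusion_gene_count"] = fusion_gene_count
    keep = density.index.difference(pd.Index(exclude))
    if len(keep) < 3:
        raise DataError("fewer than 3 chromosomes left; correlation undefined")
    sub = density.loc[keep]
    r = float(np.corrcoef(sub["genes_per_mb"], sub["fusion_gene_count"])[0, 1])
    return density, r


def per_sample_counts(
    cohort: CohortTable,
    groupby: str | None = None,
    population: str | None = None,
    threshold: int | None = None,
) -> dict:
    """Per-sample fusion totals with optional metadata grouping.

    Returns a dict with ``counts`` (per-sample Series, zeros included),
    ``groups`` (per-group n / mean / median when ``groupby`` is a metadata
    field) and ``n_above_threshold`` when a threshold is given.
    """
    samples = cohort.samples(population)
    counts = pd.Series(0, index=samples, dtype=int)
    for f in cohort.retained(population):
        counts[f.sample_id] += 1
    out: dict = {"counts": counts}
    if groupby is not None:
        try:
            labels = pd.Series(
                {s: getattr(cohort.meta[s], groupby) for s in samples}
            )
        except AttributeError:
            raise DataError(f"unknown metadata field {groupby!r}") from None
        grouped = counts.groupby(labels)
        out["groups"] = pd.DataFrame(
            {"n": grouped.size(), "mean": grouped.mean(), "median": grouped.median()}
        )
    if threshold is not None:
        out["n_above_threshold"] = int((counts > threshold).sum())
    return out
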