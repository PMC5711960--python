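"""Optional matplotlib figures for the cohort landscape (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .landscape import density_correlation
from .model import CohortTable, GeneAnnotation


def plot_burden_distribution(cohort: CohortTable, ax=None):
    """Boxplot of per-sample fusion counts, patients vs cell lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    groups, labels = [], []
    for pop in ("patient", "cell_line"):
        samples = cohort.samples(pop)
        if not samples:
            continue
        counts = {s: 0 for s in samples}
        for f in cohort.retained(pop):
            counts[f.sample_id] += 1
        groups.append(list(counts.values()))
        labels.append(pop)
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel("fusions per sample")
    return ax


def plot_density_correlation(
    cohort: CohortTable, annotation: GeneAnnotation, exclude=(), ax=None
):
    """Fusion-gene count vs gene density per chromosome (area ~ length)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    density, r = density_correlation(cohort, annotation, exclude=exclude)
    sizes = 40 * density["length_mb"] / density["length_mb"].max()
    ax.scatter(
        density["genes_per_mb"], density["fusion_gene_count"], s=sizes, alpha=0.7
    )
    for chrom, row in density.iterrows():
        ax.annotate(chrom, (row["genes_per_mb"], row["fusion_gene_count"]), fontsize=6)
    ax.set_xlabel("genes per Mb")
    ax.set_ylabel("fusion gene count")
    ax.set_title(f"Pearson r = {r:.2f}")
    return ax
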