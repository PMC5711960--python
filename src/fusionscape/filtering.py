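"""Post-consensus filters: junction read support and same-gene-family removal.

Both filters flag rather than delete: every input fusion keeps its
``passed_*`` flags so the homology score can still be reported for events
removed here. The returned list contains the fusions that pass. The filters
are monotone, idempotent and commute with each other.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import ConsensusFusion, DataError, GeneFamilyTable

__all__ = ["filter_read_support", "filter_gene_family", "apply_filters"]

#: Minimum junction-spanning read pairs required from each caller.
DEFAULT_MIN_PAIRS = 3


def filter_read_support(
    fusions: Sequence[ConsensusFusion], min_pairs: int = DEFAULT_MIN_PAIRS
) -> list[ConsensusFusion]:
    """Require at least ``min_pairs`` junction-spanning read pairs per caller.

    Both callers' counts must reach the threshold (the conservative reading:
    each caller independently re-checks its own junction evidence). Fusions
    below threshold get ``passed_support_filter = False`` and are excluded
    from the returned list.
    """
    retained = []
    for f in fusions:
        if f.junction_pairs_a < 0 or f.junction_pairs_b < 0:
            raise DataError(
                f"negative junction-pair count for {f.gene5}-{f.gene3} "
                f"in {f.sample_id}"
            )
        ok = f.junction_pairs_a >= min_pairs and f.junction_pairs_b >= min_pairs
        f.passed_support_filter = f.passed_support_filter and ok
        if f.passed_support_filter:
            retained.append(f)
    return retained


def filter_gene_family(
    fusions: Sequence[ConsensusFusion], families: GeneFamilyTable
) -> list[ConsensusFusion]:
    """Remove fusions whose partners share a gene family.

    Partners from the same family are likely alignment artifacts of high
    sequence similarity between paralogs. Genes absent from the family table
    share no family, so they are always retained.
    """
    retained = []
    for f in fusions:
        ok = not families.shared(f.gene5, f.gene3)
        f.passed_family_filter = f.passed_family_filter and ok
        if f.passed_family_filter:
            retained.append(f)
    return retained


def apply_filters(
    fusions: Sequence[ConsensusFusion],
    families: GeneFamilyTable | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[ConsensusFusion]:
    """Apply both filters; returns fusions passing both (all flags updated)."""
    filter_read_support(fusions, min_pairs=min_pairs)
    if families is not None:
        filter_gene_family(fusions, families)
    return [f for f in fusions if f.passed_all]
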