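"""Orientation-aware intersection of the two callers' fusion calls.

A fusion is treated as found by both callers when the same partner genes are
involved in the same 5'→3' orientation, regardless of differences in the
exact breakpoint predictions. Reciprocal products (A–B vs B–A) are distinct
events. Breakpoints and strands of the consensus record come from caller A
(the TopHat-style caller), whose predictions also anchor homology scoring.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .model import (
    Caller,
    CohortTable,
    ConsensusFusion,
    ConsistencyError,
    FusionCall,
    SampleMeta,
)

logger = logging.getLogger(__name__)

__all__ = ["intersect_calls", "intersect_cohort"]


def _check_single_sample(calls: Sequence[FusionCall], caller: Caller) -> str | None:
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ConsistencyError(
            f"{caller.value} call list mixes samples: {sorted(samples)}"
        )
    bad = [c for c in calls if c.caller is not caller]
    if bad:
        raise ConsistencyError(
            f"call list for {caller.value} contains calls from {bad[0].caller.value}"
        )
    return samples.pop() if samples else None


def intersect_calls(
    calls_a: Sequence[FusionCall], calls_b: Sequence[FusionCall]
) -> list[ConsensusFusion]:
    """Intersect one sample's calls from both callers at gene-pair level.

    Input lists must already be collapsed to one call per ordered gene pair
    (see :func:`fusionscape.io.collapse_calls`).
    """
    sample_a = _check_single_sample(calls_a, Caller.A)
    sample_b = _check_single_sample(calls_b, Caller.B)
    if sample_a is not None and sample_b is not None and sample_a != sample_b:
        raise ConsistencyError(
            f"caller reports are from different samples: {sample_a!r} vs {sample_b!r}"
        )
    by_pair_a: dict[tuple[str, str], FusionCall] = {}
    for c in calls_a:
        if c.pair in by_pair_a:
            raise ConsistencyError(
                f"duplicate pair {c.pair} in caller A list; collapse calls first"
            )
        by_pair_a[c.pair] = c
    by_pair_b: dict[tuple[str, str], FusionCall] = {}
    for c in calls_b:
        if c.pair in by_pair_b:
            raise ConsistencyError(
                f"duplicate pair {c.pair} in caller B list; collapse calls first"
            )
        by_pair_b[c.pair] = c
    out: list[ConsensusFusion] = []
    for pair, a in by_pair_a.items():
        b = by_pair_b.get(pair)
        if b is None:
            continue
        out.append(
            ConsensusFusion(
                sample_id=a.sample_id,
                gene5=a.gene5,
                gene3=a.gene3,
                chrom5=a.chrom5,
                bp5=a.bp5,
                chrom3=a.chrom3,
                bp3=a.bp3,
                strand5=a.strand5,
                strand3=a.strand3,
                junction_pairs_a=a.junction_pairs,
                junction_pairs_b=b.junction_pairs,
            )
        )
    return out


def intersect_cohort(
    reports: Mapping[str, tuple[Sequence[FusionCall], Sequence[FusionCall]]],
    meta: Mapping[str, SampleMeta],
) -> CohortTable:
    """Concatenate per-sample intersections and join sample metadata.

    ``reports`` maps sample id to ``(calls_A, calls_B)``. A sample with calls
    from only one caller contributes nothing to the consensus (the missing
    caller is treated as an empty report, with a warning).
    """
    fusions: list[ConsensusFusion] = []
    for sample_id, (calls_a, calls_b) in reports.items():
        if (len(calls_a) == 0) != (len(calls_b) == 0):
            logger.warning(
                "sample %s has calls from one caller only; treating the other "
                "as an empty report",
                sample_id,
            )
        fusions.extend(intersect_calls(calls_a, calls_b))
    missing = {s for s in reports if s not in meta}
    if missing:
        raise ConsistencyError(f"samples without metadata: {sorted(missing)}")
    return CohortTable(fusions, meta)
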