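"""End-to-end orchestration: consensus -> filters -> classification -> scores."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .consensus import intersect_cohort
from .filtering import DEFAULT_MIN_PAIRS, apply_filters
from .homology import ScoringParams, score_cohort
from .landscape import classify_cohort
from .model import CohortTable, FusionCall, GeneAnnotation, GeneFamilyTable, SampleMeta

__all__ = ["analyze", "analyze_simulated"]


def analyze(
    reports: Mapping[str, tuple[Sequence[FusionCall], Sequence[FusionCall]]],
    meta: Mapping[str, SampleMeta],
    annotation: GeneAnnotation,
    families: GeneFamilyTable | None = None,
    reference=None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    scoring: ScoringParams | None = None,
    flank_len: int = 20,
) -> CohortTable:
    """Run the full post-calling pipeline on normalised per-sample reports.

    Intersects the two callers per sample, applies the read-support and
    gene-family filters (flagging, not deleting), classifies fusions against
    the annotation and — when a reference sequence source is given — attaches
    breakpoint-flank homology E-scores to every consensus fusion, including
    filtered-out ones.
    """
    cohort = intersect_cohort(reports, meta)
    apply_filters(cohort.fusions, families, min_pairs=min_pairs)
    classify_cohort(cohort, annotation)
    if reference is not None:
        score_cohort(cohort.fusions, reference, params=scoring, flank_len=flank_len)
    return cohort


def analyze_simulated(
    sim,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    score_homology: bool = False,
    scoring: ScoringParams | None = None,
) -> CohortTable:
    """Run the pipeline on an in-memory :class:`~fusionscape.simulate.SimulatedCohort`."""
    return analyze(
        sim.reports(),
        sim.meta,
        sim.annotation,
        sim.families,
        reference=sim.reference if score_homology else None,
        min_pairs=min_pairs,
        scoring=scoring,
    )
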