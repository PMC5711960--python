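"""Breakpoint-flank homology scoring.

Fusions whose partner genes carry highly similar sequence around the
breakpoint are suspect: a junction-spanning read can be placed across two
paralogous or repetitive loci by the aligner without any real chimeric
transcript. To flag these, the 20 bp of sequence before and after each
partner's breakpoint are extracted (in transcription orientation) and the
two "before" flanks, and the two "after" flanks, are locally aligned.

The similarity is summarised as an expectation-style E-score
``E = K * m * n * exp(-lambda * S)`` where ``S`` is the Smith-Waterman local
alignment score, ``m`` and ``n`` the flank lengths and ``lambda`` the
Karlin-Altschul scale solved for the scoring matrix under a uniform base
composition. Smaller E means higher homology; the reported score per fusion
is the minimum of the before- and after-flank E-scores. The score is
descriptive (no default cutoff): it ranks candidate artifacts rather than
removing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from scipy.optimize import brentq

from .model import ConsensusFusion

__all__ = [
    "ScoringParams",
    "FlankPair",
    "HomologyResult",
    "karlin_altschul_lambda",
    "local_alignment_escore",
    "extract_flanks",
    "homology_score",
    "score_cohort",
]

DEFAULT_FLANK_LEN = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringParams:
    """DNA local-alignment scoring: +5/-4 with gap open/extend 12/4.

    ``K`` scales the E-value; only the ordering of E-scores is interpreted,
    so ``K`` is a documented constant rather than a fitted parameter.
    Ambiguous bases (N) score 0 against everything.
    """

    match: int = 5
    mismatch: int = -4
    gap_open: int = 12
    gap_extend: int = 4
    K: float = 0.1


@lru_cache(maxsize=8)
def karlin_altschul_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0.

    Uniform base composition (p=1/4): 4 matching and 12 mismatching ordered
    base pairs out of 16.
    """

    def f(lam: float) -> float:
        return (4 * math.exp(lam * match) + 12 * math.exp(lam * mismatch)) / 16 - 1

    # lambda = 0 is always a root; the positive root is the one of interest.
    lo = 1e-4
    while f(lo) > 0:  # pragma: no cover - defensive for unusual matrices
        lo /= 10
    return float(brentq(f, lo, 10.0))


@lru_cache(maxsize=8)
def _aligner(params: ScoringParams):
    from Bio import Align
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = params.match if a == b else params.mismatch
    # N is ambiguity, not evidence: contributes nothing either way
    for a in "ACGTN":
        mat["N", a] = 0.0
        mat[a, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -float(params.gap_open)
    aligner.extend_gap_score = -float(params.gap_extend)
    return aligner


def _clean(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in "ACGTN" else "N" for c in seq)


def local_alignment_escore(
    seq1: str, seq2: str, params: ScoringParams | None = None
) -> float:
    """E-score of the best local alignment between two DNA sequences.

    Smaller values mean stronger similarity; identical sequences minimise the
    E-score among all pairs of the same lengths. Raises ``ValueError`` on an
    empty sequence.
    """
    if params is None:
        params = ScoringParams()
    if not seq1 or not seq2:
        raise ValueError("cannot score an empty sequence")
    seq1, seq2 = _clean(seq1), _clean(seq2)
    score = float(_aligner(params).score(seq1, seq2))
    lam = karlin_altschul_lambda(params.match, params.mismatch)
    return params.K * len(seq1) * len(seq2) * math.exp(-lam * score)


@dataclass(frozen=True)
class FlankPair:
    """Breakpoint flanks for both partners, in transcription orientation.

    ``up*`` end at the breakpoint base; ``down*`` start at the next base.
    ``truncated`` marks flanks shortened at a contig edge.
    """

    up5: str
    up3: str
    down5: str
    down3: str
    truncated: bool = False


@dataclass(frozen=True)
class HomologyResult:
    e_before: float
    e_after: float

    @property
    def score(self) -> float:
        return min(self.e_before, self.e_after)


def _contig(reference, chrom: str):
    try:
        return reference[chrom]
    except KeyError:
        raise LookupError(f"contig {chrom!r} not found in reference") from None


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """1-based inclusive substring of a contig (pyfaidx Fasta or plain dict)."""
    contig = _contig(reference, chrom)
    piece = contig[start - 1 : end]
    seq = getattr(piece, "seq", piece)
    return str(seq).upper()


def _one_gene_flanks(
    reference, chrom: str, bp: int, strand: str, flank_len: int
) -> tuple[str, str, bool]:
    clen = len(_contig(reference, chrom))
    if not 1 <= bp <= clen:
        raise LookupError(f"breakpoint {bp} outside contig {chrom!r} (len {clen})")
    if strand == "+":
        b_start, b_end = max(1, bp - flank_len + 1), bp
        a_start, a_end = bp + 1, min(clen, bp + flank_len)
        before = _fetch(reference, chrom, b_start, b_end)
        after = _fetch(reference, chrom, a_start, a_end) if a_start <= a_end else ""
    else:
        # minus strand: transcription runs right-to-left on the genome, so the
        # flanks are the mirrored windows, reverse complemented
        b_start, b_end = bp, min(clen, bp + flank_len - 1)
        a_start, a_end = max(1, bp - flank_len), bp - 1
        before = reverse_complement(_fetch(reference, chrom, b_start, b_end))
        after = (
            reverse_complement(_fetch(reference, chrom, a_start, a_end))
            if a_start <= a_end
            else ""
        )
    truncated = len(before) < flank_len or len(after) < flank_len
    return before, after, truncated


def extract_flanks(
    fusion: ConsensusFusion, reference, flank_len: int = DEFAULT_FLANK_LEN
) -> FlankPair:
    """Extract both partners' breakpoint flanks from the reference.

    Flanks are read in transcription orientation (reverse complemented for
    minus-strand genes). A breakpoint within ``flank_len`` of a contig edge
    yields a truncated, flagged flank; an unknown contig raises
    ``LookupError``.
    """
    up5, down5, t5 = _one_gene_flanks(
        reference, fusion.chrom5, fusion.bp5, fusion.strand5, flank_len
    )
    up3, down3, t3 = _one_gene_flanks(
        reference, fusion.chrom3, fusion.bp3, fusion.strand3, flank_len
    )
    return FlankPair(up5=up5, up3=up3, down5=down5, down3=down3, truncated=t5 or t3)


def homology_score(
    fusion: ConsensusFusion,
    reference,
    params: ScoringParams | None = None,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> HomologyResult:
    """Score one fusion's breakpoint-flank homology and attach it.

    The two partners' before-flanks are aligned against each other, likewise
    the two after-flanks; the reported score is the minimum of the two
    E-scores (most-similar side wins).
    """
    flanks = extract_flanks(fusion, reference, flank_len=flank_len)
    result = HomologyResult(
        e_before=local_alignment_escore(flanks.up5, flanks.up3, params),
        e_after=local_alignment_escore(flanks.down5, flanks.down3, params),
    )
    fusion.homology_escore = result.score
    return result


def score_cohort(
    fusions,
    reference,
    params: ScoringParams | None = None,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> None:
    """Attach homology E-scores to every fusion (including filtered-out ones)."""
    for f in fusions:
        homology_score(f, reference, params=params, flank_len=flank_len)
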