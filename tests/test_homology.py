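"""Flank extraction and local-alignment E-scores.

The independent oracle is a hand-written Gotoh dynamic program (local
alignment with affine gaps), checked against the package's aligner on short
sequences.
"""

import math

import numpy as np
import pytest

from conftest import make_fusion
from fusionscape.homology import (
    ScoringParams,
    extract_flanks,
    homology_score,
    karlin_altschul_lambda,
    local_alignment_escore,
    reverse_complement,
)

PARAMS = ScoringParams()


def sw_oracle(s1: str, s2: str, p: ScoringParams = PARAMS) -> float:
    """Brute-force local alignment score (Gotoh DP, affine gaps).

    Gap of length L costs open + (L-1)*extend, matching the package's
    aligner configuration.
    """
    n, m = len(s1), len(s2)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if s1[i - 1] == s2[j - 1] else p.mismatch
            if "N" in (s1[i - 1], s2[j - 1]):
                s = 0
            M[i][j] = max(
                0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            )
            Ix[i][j] = max(
                max(M[i - 1][j], Iy[i - 1][j]) - p.gap_open, Ix[i - 1][j] - p.gap_extend
            )
            Iy[i][j] = max(
                max(M[i][j - 1], Ix[i][j - 1]) - p.gap_open, Iy[i][j - 1] - p.gap_extend
            )
            best = max(best, M[i][j])
    return best


def escore_from_sw(score: float, m: int, n: int, p: ScoringParams = PARAMS) -> float:
    lam = karlin_altschul_lambda(p.match, p.mismatch)
    return p.K * m * n * math.exp(-lam * score)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestEscore:
    def test_agrees_with_dp_oracle_on_short_sequences(self, rng):
        for _ in range(80):
            s1 = random_dna(rng, int(rng.integers(3, 13)))
            s2 = random_dna(rng, int(rng.integers(3, 13)))
            expected = escore_from_sw(sw_oracle(s1, s2), len(s1), len(s2))
            assert local_alignment_escore(s1, s2) == pytest.approx(expected)

    def test_identity_minimises_e_for_fixed_lengths(self, rng):
        s = random_dna(rng, 20)
        e_id = local_alignment_escore(s, s)
        for _ in range(200):
            other = random_dna(rng, 20)
            if other == s:
                continue
            assert e_id < local_alignment_escore(s, other)

    def test_shuffled_partner_scores_near_null(self, rng):
        # a random shuffle destroys homology: E should sit orders of
        # magnitude above the identity score
        s = random_dna(rng, 20)
        shuffled = "".join(rng.permutation(list(s)))
        assert local_alignment_escore(s, shuffled) > 1e-3
        assert local_alignment_escore(s, s) < 1e-6

    def test_e_strictly_decreasing_in_shared_substring_length(self, rng):
        core = random_dna(rng, 16)
        scores = []
        for k in (8, 12, 16):
            left = random_dna(rng, 20 - k)
            right = random_dna(rng, 20 - k)
            s1 = (random_dna(rng, 2) + core[:k] + random_dna(rng, 20))[:20]
            s2 = (left + core[:k] + right)[:20]
            scores.append(local_alignment_escore(s1, s2))
        assert scores[0] > scores[1] > scores[2]

    def test_symmetry(self, rng):
        for _ in range(25):
            s1, s2 = random_dna(rng, 20), random_dna(rng, 20)
            assert local_alignment_escore(s1, s2) == pytest.approx(
                local_alignment_escore(s2, s1)
            )

    def test_ambiguity_bases_score_zero(self):
        assert local_alignment_escore("NNNNNNNN", "NNNNNNNN") == pytest.approx(
            escore_from_sw(0, 8, 8)
        )

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            local_alignment_escore("", "ACGT")


TOY_CONTIG = "ACGTACGTTGCATGCAAAACCCGGGTTTACGTACGTACGT"  # 40 bp
TOY_REF = {"chrT": TOY_CONTIG}


class TestFlankExtraction:
    def test_plus_strand_coordinates(self):
        f = make_fusion(chrom5="chrT", bp5=10, chrom3="chrT", bp3=30, strand3="+")
        flanks = extract_flanks(f, TOY_REF, flank_len=4)
        assert flanks.up5 == TOY_CONTIG[6:10]  # bases 7-10, ends at breakpoint
        assert flanks.down5 == TOY_CONTIG[10:14]  # bases 11-14
        assert flanks.up3 == TOY_CONTIG[26:30]
        assert flanks.down3 == TOY_CONTIG[30:34]
        assert not flanks.truncated

    def test_minus_strand_is_reverse_complement_of_mirrored_window(self):
        f = make_fusion(chrom5="chrT", bp5=10, strand5="-", chrom3="chrT", bp3=30)
        flanks = extract_flanks(f, TOY_REF, flank_len=4)
        assert flanks.up5 == reverse_complement(TOY_CONTIG[9:13])  # bases 10-13
        assert flanks.down5 == reverse_complement(TOY_CONTIG[5:9])  # bases 6-9

    def test_single_base_flanks(self):
        f = make_fusion(chrom5="chrT", bp5=10, chrom3="chrT", bp3=30)
        flanks = extract_flanks(f, TOY_REF, flank_len=1)
        assert len(flanks.up5) == len(flanks.down3) == 1

    def test_contig_edge_truncates_and_flags(self):
        f = make_fusion(chrom5="chrT", bp5=2, chrom3="chrT", bp3=30)
        flanks = extract_flanks(f, TOY_REF, flank_len=5)
        assert flanks.truncated
        assert flanks.up5 == TOY_CONTIG[:2]

    def test_unknown_contig_raises_lookup_error(self):
        f = make_fusion(chrom5="chrMISSING", bp5=10, chrom3="chrT", bp3=30)
        with pytest.raises(LookupError):
            extract_flanks(f, TOY_REF)


class TestHomologyScore:
    def test_score_is_min_of_before_and_after(self):
        # gene3 window copies gene5's before-flank only
        ref = {"chrT": TOY_CONTIG, "chrU": TOY_CONTIG[:20] + "GGGGGGGGGGGGGGGGGGGG"}
        f = make_fusion(chrom5="chrT", bp5=10, chrom3="chrU", bp3=10)
        res = homology_score(f, ref, flank_len=6)
        assert res.score == min(res.e_before, res.e_after)
        assert f.homology_escore == res.score

    def test_identical_flanks_reach_identity_escore(self):
        ref = {"c1": TOY_CONTIG, "c2": TOY_CONTIG}
        f = make_fusion(chrom5="c1", bp5=15, chrom3="c2", bp3=15)
        res = homology_score(f, ref, flank_len=8)
        assert res.e_before == pytest.approx(escore_from_sw(8 * PARAMS.match, 8, 8))

    def test_planted_decoys_score_below_true_fusions(self, tiny_sim, tiny_cohort):
        from fusionscape.homology import score_cohort

        score_cohort(tiny_cohort.fusions, tiny_sim.reference)
        decoys, trues = [], []
        for r in tiny_sim.truth.records:
            key = (r["sample_id"], r["gene5"], r["gene3"])
            for f in tiny_cohort.fusions:
                if (f.sample_id, f.gene5, f.gene3) == key:
                    if r["label"] == "homology_decoy":
                        decoys.append(f.homology_escore)
                    elif r["label"] == "true":
                        trues.append(f.homology_escore)
        assert decoys, "fixture should plant at least one homology decoy"
        assert max(decoys) < np.median(trues)
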