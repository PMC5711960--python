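# Methods

## Scope and data model

`fusionscape` operates strictly downstream of fusion calling: its inputs are
two callers' per-sample report tables (TopHat-Fusion-style and
MapSplice-style TSV dialects), a gene annotation (GFF3/GTF), an HGNC-style
gene-family table, a reference sequence source and optional sample metadata
and a log-normalised expression matrix. Read alignment, the callers
themselves, and wet-lab validation are out of scope.

Coordinates are stored 1-based inclusive internally; each report dialect
declares its source convention (the TopHat-style dialect is 0-based, the
MapSplice-style dialect 1-based) and the reader converts on input.
Chromosome names are normalised to the annotation's namespace by
adding/stripping the `chr` prefix. Within one caller's report, several rows
for the same (sample, ordered gene pair) are collapsed to the row with the
maximum junction-pair count before any intersection, because the consensus
rule is defined at gene-pair level.

A fusion event is an **ordered** pair (5′ gene, 3′ gene): the reciprocal
products of a balanced translocation are distinct events. "Found by both
callers" therefore means the identical ordered pair in the same sample;
strand columns are not additionally compared, and breakpoint coordinates
may differ freely between callers. Consensus records carry the TopHat-style
caller's breakpoints and strands, which also anchor homology scoring; the
other caller contributes only its read count. This choice is applied
uniformly (one coordinate authority) rather than attempting breakpoint
reconciliation.

## Filters

* **Read support.** A consensus fusion needs ≥ `min_pairs` (default 3)
  junction-spanning read pairs *from each caller*. The both-must-pass
  reading is the conservative interpretation of re-checking both callers'
  junction evidence and is configurable.
* **Gene family.** Partners sharing any gene-family identifier are removed;
  genes absent from the family table share nothing. The rationale is that
  paralogous families carry enough sequence similarity for junction reads
  to cross-map.

Both filters set flags (`passed_support_filter`, `passed_family_filter`)
instead of deleting rows, so the homology score is still reported for
removed candidates. The filters are monotone, idempotent, and commute.

## Breakpoint-flank homology E-score

For each fusion the 20 bp immediately before (ending at the breakpoint
base) and after (starting at the next base) each partner's breakpoint are
extracted in transcription orientation (reverse complemented for minus-
strand genes; flanks truncated at contig edges are flagged). The two
"before" flanks are locally aligned against each other, likewise the two
"after" flanks — a cross-partner comparison, since the artifact mechanism
is one read being placeable on both partners.

Alignment is Smith–Waterman with match +5, mismatch −4, and affine gaps
costing 12 for the first gapped base and 4 for each additional one
(Biopython's `PairwiseAligner` in local mode; `N` scores 0 against
everything). The score `S` is converted to an expectation-style value
`E = K·m·n·exp(−λS)` with `m, n` the flank lengths. λ is the positive root
of `Σᵢⱼ pᵢpⱼ exp(λ sᵢⱼ) = 1` under uniform base composition, solved
numerically (λ ≈ 0.192 for +5/−4); `K = 0.1` is a fixed constant. Because
`K` only rescales every E-value by the same factor, the score's *ordering*
— which is all that is interpreted — does not depend on it; no numeric
parity with any external aligner's E-value is claimed. Smaller E means
stronger flank homology. No default cutoff is applied: the score is
descriptive, written to the fusion table, with an optional threshold
available to callers.

Correctness is checked against an independently written Gotoh dynamic
program on short sequences, and the score separates planted homologous
flanks (18/20 identical bases) from unrelated flanks by several orders of
magnitude.

## Landscape statistics

* **Unique fusion** — a distinct ordered pair; **recurrent** — observed in
  ≥ 2 samples of the same population (patients and cell lines counted
  separately).
* The unique-pair decomposition reported is: Ig fusions, recurrent non-Ig
  fusions, and "others" (neither), which sum to 100%; the overall recurrent
  share is reported alongside because it overlaps Ig. "Other — same chr" is
  the share of others whose partners lie on the same chromosome with gene
  spans separated by < 10 Mb.
* The < 10 Mb rule uses the *gap between gene spans* (0 when overlapping),
  the natural anchor for read-through candidates; anchoring on gene starts
  would misclassify long genes.
* Ig classification uses a symbol rule: prefix IGH/IGK/IGL followed by a
  segment or constant-region designator (IGHM, IGHG1, IGKC, IGKV3-20, …)
  with an explicit exclusion list (IGHMBP2 by default) for non-locus genes
  that merely share the prefix. The IGH/IGK/IGL split of Ig fusions is
  reported both over unique Ig pairs and over all Ig events, since either
  denominator is defensible.
* The gene-density correlation counts, per chromosome, the partner genes of
  every fusion (an intra-chromosomal fusion counts twice on its
  chromosome), so counts sum to exactly twice the number of fusions, and
  correlates this with genes per Mb across chromosomes, optionally
  excluding outlier chromosomes (e.g. the Ig loci).

## Permutation tests and expression comparisons

Group comparisons of per-sample fusion counts use permutation tests: the
two-sample Kolmogorov–Smirnov statistic (99,999 permutations by default,
used for patients vs cell lines) and the absolute difference in means
(9,999 permutations, used for the Ig/non-Ig, FISH-translocated, and
high-hyperdiploid contrasts). Empirical p-values use the add-one estimator
`p = (1 + #{permuted ≥ observed})/(1 + N)` — never zero, exactly
reproducible under a fixed seed, and conservative. The KS statistic is
evaluated only at attained pooled values, so tied counts are handled as in
the classical statistic. Note that with small equal group sizes the KS
statistic lives on a coarse lattice and ties make any permutation p-value
conservative; calibration experiments should use group sizes with a large
least common multiple.

Fused-vs-unfused expression uses two-sided Student t-tests per gene on
log-normalised values, restricted by default to the 36 most recurrent
partner genes (ranked by number of fused samples), with Benjamini–Hochberg
adjustment across the tested genes (Holm/Bonferroni configurable; the
adjustment method is a modelling choice since only "corrected for multiple
testing" is specified upstream). Genes with fewer than two fused or two
unfused samples are flagged untestable and excluded from the adjustment.
Burden–covariate association (e.g. age) is Spearman's ρ with a two-sided
permutation p-value.

All randomness flows through an explicit seed or `numpy.random.Generator`;
there is no global RNG state.

## Synthetic cohort generator

The generator emulates, at desk scale, the structure of a myeloma fusion
cohort: 255 patients and 71 cell lines by default.

**Genome.** 22 toy chromosomes of 360–900 kb with ~870 genes; gene density
spans a >3× range with a dense chromosome-19 analog; IGH/IGK/IGL locus
genes sit on chr14/chr2/chr22; two gene families (histone-H2B-like and
KRTAP-like) provide same-family decoy material; alias symbols (WHSC1,
MMSET → NSD2) exercise alias resolution. Sequence is i.i.d. uniform ACGT,
generated lazily from a dedicated seed stream.

**Burden.** Patient fusion counts are zero-inflated negative binomial
(dispersion r = 2); the preset solves the inflation π and NB mean µ from
the targets mean = 5.5 and zero fraction = 11.8%. Cell lines use a
zero-truncated NB (mean 6.1, r = 8): every cell line has ≥ 1 fusion and a
lighter tail, so the patient distribution is the right-skewed one.

**Ig structure.** Each patient belongs to a cytogenetic group
(translocated 35%, high-hyperdiploid 20%, other) and a light-chain
phenotype (kappa 68%). Given burden *n*, the patient is "Ig-type" with
probability `clip(m_g·(a + b·n), 0, 1)` — the group multiplier m_g makes
translocated patients Ig-rich and high-hyperdiploid patients Ig-poor — and
each of an Ig-type patient's events is an Ig fusion with probability θ.
The Ig class of an event depends on group and phenotype (translocated →
IGH-heavy; kappa phenotype → IGK, lambda → IGL), creating the
translocation/IGH and phenotype/light-chain couplings.

**Recurrence.** Events are either hotspot (drawn from per-class catalogs of
pairs with heavy-tailed Zipf intensities, including an IGHM–NSD2-like pair
and one dominant IGK partner) or fresh singletons (Ig gene × random
partner, or non-Ig pairs that are same-chromosome with probability 0.55,
chr19-weighted). Pairs are unique within a sample; a hotspot draw whose
pair is already present falls back to a fresh singleton.

**Calibration.** The preset solves five parameters (a, b, θ, and the two
hotspot probabilities) from five targets — 47.3% of patients with an Ig
fusion, conditional burden 8.3 with-Ig, Ig share 36% of unique pairs,
recurrent 28.8%, recurrent non-Ig 17.2% — using exact ZINB expectations
and Poissonized hotspot-occupancy formulas that account for per-sample
deduplication and the hotspot→singleton fallback. The solve is
deterministic (trust-region least squares) and raises an error when a
configuration cannot reach its targets. End-to-end recovery of the target
statistics across 20 seeds is part of the test suite.

**Noise and decoys.** True events appear in both callers (≥ 3 junction
pairs each, counts 3 + NB; the MapSplice-style report gets N(0, 15 bp)
breakpoint jitter and occasional duplicate rows with weaker support);
caller-specific false positives (Poisson rates 4.0 / 2.5 per sample)
appear in exactly one caller and are pair-disjoint from everything else;
same-family decoys and low-support events appear in both callers; a
fraction (8%) of fresh true events are homology decoys whose breakpoint
flanks are copied (with 2 mismatches) into the partner locus when the
reference is built. Every emitted row is labelled in the ground-truth
table.

**Expression.** Genes × samples log-scale matrix: per-gene baseline
U(4, 10) plus N(0, 1) noise; samples fused for a gene get a +2 log-unit
shift (+4 for NSD2, giving the clean bimodal separation characteristic of
t(4;14)). **Age** is coupled to burden through a Gaussian copula
(ρ = 0.35) around mean 56.6.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: read-level artifacts (the callers are
simulated only through their report rows), correlated false positives
between callers (real callers share failure modes; consensus precision is
1 by construction here), repeat/Alu-driven homology structure beyond the
planted decoys, genome-scale coordinates (chromosomes are ~500 kb, so every
same-chromosome event is trivially < 10 Mb apart), expression normalisation
(inputs are assumed pre-normalised), and survival structure. Absolute
counts (e.g. the number of unique pairs, ~500) emerge from the catalog
sizes and are not calibrated targets.

## Numerical choices and problem sizes

* Permutation engines are vectorised over batches of label permutations;
  comparisons use `≥ observed − 1e−12` so that bitwise-equal statistics
  count as ties.
* The calibration pmf grid truncates burden at n = 150 (ZINB tail mass
  < 1e−12 there).
* Tests run the full pipeline on 20 preset-sized cohorts (255 patients) for
  parameter recovery and on smaller 20–30-sample cohorts elsewhere; the
  whole suite completes in well under a minute on one core, which is the
  intended desk-scale operating point of the generator.
* Degenerate inputs: empty report files yield empty call lists; an empty
  cohort yields an all-zero summary; correlation over fewer than 3
  chromosomes, empty permutation groups, constant covariates and negative
  read counts raise typed errors.

## Known limitations

* The E-score's `K` (and gapped-λ approximation by the ungapped solution)
  make its absolute scale conventional; only orderings are meaningful.
* The Ig symbol rule depends on annotation symbol hygiene; unusual locus
  symbols need the exclusion/alias tables.
* Recurrence is counted within population only; no cross-population
  recurrence notion is implemented.
* The mean-difference test is two-sided on |Δmean|; directional one-sided
  variants are not exposed.
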