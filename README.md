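# fusionscape

Post-processing and cohort analysis of expressed fusion genes called from
bulk RNA-seq, modelled on the fusion landscape of multiple myeloma — a
plasma-cell malignancy whose biology is dominated by translocations into the
immunoglobulin heavy- (IGH, 14q32), kappa- (IGK, 2p11) and lambda-chain
(IGL, 22q11) loci.

Fusion callers disagree wildly and produce many alignment artifacts, so the
package implements a conservative consensus strategy over two callers
(a TopHat-Fusion-style and a MapSplice-style report dialect) followed by
explicit filters and a homology diagnostic:

1. **Consensus** — a fusion is kept when both callers report the same
   ordered partner pair (5′ gene, 3′ gene) in the same sample, regardless of
   breakpoint differences. Orientation matters: *IGH–NSD2* and *NSD2–IGH*
   are different events.
2. **Read support** — at least 3 junction-spanning read pairs from each
   caller (for the MapSplice-style dialect this is the sum of the multiple-
   and unique-mapped paired read counts).
3. **Gene family** — fusions whose partners share an HGNC-style gene family
   are removed as likely paralog cross-alignments. Filtered events are
   flagged, not deleted, so downstream scores cover them too.
4. **Breakpoint-flank homology** — for each fusion the 20 bp before and
   after each partner's breakpoint are extracted in transcription
   orientation and aligned across partners (Smith–Waterman, +5/−4, gap
   open/extend 12/4). Similarity is summarised as a Karlin–Altschul
   E-score `E = K·m·n·exp(−λS)`; the reported score is
   `min(E_before, E_after)`, where small values flag homology-driven
   artifacts.

On top of the consensus table the package computes the cohort landscape —
unique pairs (distinct ordered partner pairs), recurrent pairs (seen in ≥2
samples of a population), Ig fusions, same-chromosome <10 Mb read-through
candidates, per-chromosome fusion counts vs gene density — and the cohort
statistics: permutation tests (Kolmogorov–Smirnov and mean-difference, with
the add-one estimator `p = (1+k)/(1+N)`), fused-vs-unfused expression
t-tests with multiple-testing correction, and burden–covariate Spearman
associations.

A first-class synthetic-cohort generator (`fusionscape.simulate`) emits a
toy genome, both callers' reports, metadata, expression and ground truth
with the statistical structure the analysis assumes, so the entire pipeline
is testable without any data downloads. See `docs/methods.md` for the
model, its calibration and its limitations.

## Worked example

```python
from fusionscape import (
    myeloma_preset, simulate_cohort, analyze_simulated, summarize_landscape,
)
from fusionscape.stats import mean_diff_permutation_test

sim = simulate_cohort(myeloma_preset(seed=1))          # 255 patients, 71 cell lines
cohort = analyze_simulated(sim, score_homology=True)
summary = summarize_landscape(cohort, population="patient")

counts = summary.per_sample_counts
print(f"mean burden: {counts.mean():.2f}, fusion-free: {100*(counts==0).mean():.1f}%")
print(f"unique pairs: {summary.n_unique_pairs}")
print(f"Ig: {summary.pct_ig_of_unique:.1f}%  recurrent: {summary.pct_recurrent_of_unique:.1f}%")

ig = {f.sample_id for f in cohort.retained("patient") if f.is_ig}
nz = counts[counts > 0]
x, y = nz[nz.index.isin(ig)], nz[~nz.index.isin(ig)]
res = mean_diff_permutation_test(x, y, seed=0)
print(f"burden with/without Ig fusion: {x.mean():.1f} vs {y.mean():.1f} (p = {res.p_value:.4f})")
```

prints (seed 1):

```
mean burden: 5.60, fusion-free: 15.3%
unique pairs: 504
Ig: 31.3%  recurrent: 28.0%
burden with/without Ig fusion: 8.3 vs 4.2 (p = 0.0001)
```

The mean burden sits at the generator's configured 5.5 up to sampling
noise; patients carrying an Ig fusion have roughly twice the burden of
those without, and the permutation p-value is at the resolution floor of
9,999 permutations. `summary.per_gene_counts` ranks partner genes — in this
cohort the chromosome-19 read-through pair *TPM4–ISYNA1* and the kappa
locus *IGKC* top the list, each fused in ~60 samples.

There is also a thin CLI: `fusionscape simulate`, `fusionscape normalize`,
`fusionscape intersect`, `fusionscape summarize`, `fusionscape stats`
(see `--help`).

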