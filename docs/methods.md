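# Methods

## Model and assumptions

The package infers fusion transcripts (read-through / cis-SAGe chimeras
and genomic gene fusions) from poly(A)-capture spatial-transcriptomics
counts. The underlying biological model: polyadenylation of a chimera
happens once, downstream of the 3′ parental gene, so in fused cells the
5′ gene contributes no captured molecules while the 3′ gene's captured
count reflects the (typically strong) 5′ promoter. Three consequences
are exploited:

1. **C-score.** For each spot `s`, both parental genes are expressed
   relative to the section mean, `R = x(s) / mean(x)`, and the larger
   ratio wins with a sign: `C = −R5′` when `R5′ ≥ R3′`, else `C = +R3′`.
   The statistic assumes the section mean is a meaningful reference —
   i.e. that the fusion is absent from (or rare in) most of the section,
   and that both genes are well enough expressed for ratios to be
   informative. Ratios of an all-zero gene are defined as 0 (a 0/0
   convention) rather than an error, because a silenced 5′ gene is
   exactly the fusion signature; the tie `R5′ = R3′` resolves to the
   absence branch by the definition's `≥`. Ratios use the spot's *own*
   section mean when several sections are analysed.
2. **Diversity index.** A fused pair's C-scores mix an absence regime
   (mirroring 5′ expression) with an occurrence regime (mirroring fusion
   expression), so they visit many distinct values. After rounding to
   one decimal (half away from zero — the grade-school rule; numpy's
   half-to-even would differ on exact ties), `N` counts nonzero scores,
   `U` distinct nonzero scores, and `D = N × U`. Rounding doubles as a
   noise floor: magnitudes below 0.05 count as zero. `D` is a ranking
   statistic only; no null distribution is attached.
3. **Poly(A) classifier.** With per-gene tail counts, `count5 ≤ t <
   count3` is the fusion pattern, tails on both genes the trans-splicing
   pattern, and no 3′ tails `undetected` regardless of the 5′ count (a
   3′-silent pair carries no chimera evidence either way; this fourth
   case is not distinguished further). The tolerance `t` (default 0)
   absorbs spurious single tails if raised. The classifier cannot
   separate cis-SAGe from genomic fusion — both silence the 5′ tail —
   and is blind to chimeras whose parents both stay polyadenylated, as a
   documented inversion case illustrates.

## Labelling conventions

Two printed conventions coexist for the occurrence/absence split:
*strict* (absence `C < 0`, occurrence `C > 0`, `C = 0` neutral and
excluded from DE groups) and *fig3* (absence `C ≤ 0`, no neutral class).
Both are implemented; DE uses strict, the grade-fraction summaries use
fig3. Grades split each side at ±`mild` (default 1): mild occurrence
`0 < C < 1`, strong occurrence `C ≥ 1`, mirrored for absence. With
pseudocounted ratios (`(x+1)/(mean+1)`, used to avoid 0/0) scores never
reach 0, so an `occ_threshold` flag shifts the occurrence boundary; its
default is 0, i.e. identical to the strict rule.

## Preprocessing (DE branch only)

C-scores are computed on the raw, unfiltered matrix — the score is a
per-spot ratio statistic and needs no QC; quality control feeds only the
differential-expression branch:

- **Spot QC**: drop spots with natural-log library size below
  `median − 3 × MAD`, using the raw MAD (no 1.4826 consistency factor —
  the rule is stated in raw MADs). Zero-count spots are always dropped.
- **Gene filter**: keep genes with total count ≥ 5 detected in ≥ 3
  spots (both configurable; "close to zero" has no canonical value).
- **Normalization**: per-section size factors, mean 1, with
  `values = counts / sf`. Default is library-size factors
  (`sf = lib/mean(lib)`). A simplified pooled-deconvolution option
  exists for fidelity to scran-style normalization: spots ring-ordered
  by library size, sliding pools of sizes {21, 41, 61} (clipped to the
  section size), each pool's factor estimated as the median ratio of the
  pooled profile to the average-spot profile, individual factors
  recovered by sparse least squares with a weak (λ = 0.1) ridge toward
  library-size factors; sections smaller than the smallest pool fall
  back to library-size factors with a warning. The C-score itself uses
  raw counts relative to section means and is unaffected by either
  choice.
- **Variability filter**: among the spots entering DE, drop genes whose
  sample standard deviation is below 10% of their mean (and zero-mean
  genes).

## Differential expression and spatial statistics

Occurrence vs absence spots are compared per gene by fold change
(occurrence mean / absence mean of normalized values; +∞ sentinel when
the absence mean is 0) and a two-sample t-test. Welch's unequal-variance
form is the default — the procedure's ecosystem default and the safer
choice for unequal group sizes; the pooled-variance form is available.
Genes with zero variance in both groups and equal means are defined as
t = 0, p = 1. P-values get Benjamini–Hochberg adjustment; genes with
q < 0.1 are exported (ordered by q, then |log fold change|) for external
pathway enrichment, which is out of scope here.

C-score maps are related to factor-activity maps by Pearson (raw
values) and Spearman (average ranks for ties) correlation over all
shared spots of a section, with two-sided p-values from the
t-approximation; constant inputs raise rather than return NaN. Grade
fractions are taken over spots whose factor activity exceeds a strict
threshold (default 0.2 on the [0, 1] activity scale).

## Synthetic tissue generator

The generator emulates the data shape the method targets: a 33 × 31
array (1023 spots, close to published ~1007-spot prostate sections)
by default 2000 genes (scalable to the full ~5000). Components:

- **Counts**: gamma-Poisson (negative binomial), `var = m + m²/r` with
  size `r = 50` — moderate overdispersion for UMI-like spot data.
  Per-gene baseline means are lognormal (meanlog −1, sdlog 1.5, i.e.
  mostly sparse genes with a long expressed tail); a lognormal per-spot
  library multiplier (sdlog 0.2) models capture-efficiency variation.
- **Factors**: three radial blobs (normal glands, PIN glands, cancer)
  with activity `exp(−d²/2σ²)` of distance to the centre, clipped below
  0.01; each multiplicatively boosts a random 100-gene subset with
  exponential loadings where active.
- **Planted fusion**: the pair defaults to well-expressed genes — 3′
  baseline mean 20 counts/spot, 5′ promoter strength μ5 = 100 (5× that
  baseline), reflecting that the known read-through pairs involve
  highly expressed genes. In spots of the cancer region (activity >
  0.3) with fusion burden `f` (default 1), expression is *transferred*:
  the 5′ mean becomes `(1−f)·μ5` and the 3′ mean `base3 + f·μ5`.
  Transfer rather than plain zeroing lets partial burden represent
  spots whose cell mixture is only partly fused; `f = 1` recovers the
  idealised fully-fused case. Pair genes carry no factor loadings, so
  the fusion is the only systematic signal on them.

Everything is deterministic given the config seed.

What the generator does **not** emulate: spot-to-spot spatial
correlation of noise, segmentation/annotation structure beyond radial
blobs, gene–gene correlation outside the factor loadings, ambient RNA,
or TAIL-seq read-level artefacts (the poly(A) fixtures draw Poisson tail
counts directly). Passing recovery tests therefore demonstrates that
the statistics behave as designed under their own model assumptions, not
that real-tissue performance matches; the published real-data
correlations are far weaker (Pearson ρ ≈ 0.1–0.25 between C-score and
disease-factor activity) than on this clean simulation.

## Numerical choices and degenerate inputs

- Rounding for `D`: half away from zero, applied before the ≠ 0 test.
- Signed zero C-scores collapse to plain 0.0.
- Candidate-pair gap: `start(downstream) − end(upstream)`, overlap = 0;
  boundary inclusive at 30 000 bp; upstream partner is 5′ (smaller
  coordinates on `+`, larger on `−`).
- Screen tie-break: D descending, then N descending, then pair name.
- Size factors are renormalized to mean 1 within 1e−9; non-positive
  pooled solutions (pathological fits) are floored and renormalized.
- BH adjustment is monotone and dominates the identity but is *not*
  idempotent; the suite checks the true properties.
- Fold change 0/0 is NaN, `x/0` (x > 0) is +∞.
- All TSV I/O is strict: negative/non-integer counts, malformed
  `NxM` spot IDs, duplicate gene symbols, and out-of-range activities
  are rejected with the offending cell named.

## Problem sizes

The test suite and the reproduction script run sections of 1023 spots ×
2000 genes, 200-pair screens, and 50-replicate oracle comparisons;
these sizes keep every statistic's behaviour visible (binomial 99%
calibration bands, rank-1 recovery) while completing in seconds.

## Known limitations

- The diversity index has no significance calibration; ranks only.
  Under strong spatially structured expression, non-fused gene pairs
  with high factor loadings can approach the planted pair's D.
- The C-score reference (section mean) biases ratios when the fusion
  occupies a large fraction of the section.
- The trans-splicing pattern is indistinguishable from ordinary
  co-expression of an unfused pair; calls are patterns, not mechanisms.
- The DE t-test operates on normalized counts, not a count model; with
  ~500 spots per group it is well calibrated on the generator's data,
  but very sparse genes are filtered rather than modelled.
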