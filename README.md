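# stfusion

Fusion-transcript inference from poly(A)-capture spatial transcriptomics
(ST) data.

## The problem

Chimeric RNAs — read-through transcripts of adjacent genes (cis-SAGe),
genomic gene fusions, and trans-splicing hybrids — are important cancer
biomarkers, but standard chimera callers work on bulk RNA-seq and lose
all spatial information. ST arrays capture transcripts by their poly(A)
tails at ~1000 barcoded spots per tissue section, which enables an
indirect detection route: a chimera produced by read-through or genomic
fusion carries **no poly(A) tail on its 5′ parental gene** while the 3′
gene's tail count is driven by the 5′ promoter. The 5′ gene's apparent
expression collapses and the 3′ gene's is elevated — a signature visible
in ordinary spot × gene count matrices.

`stfusion` implements three connected analyses around this signature:

**Per-spot C-score** for a candidate pair (gene5′, gene3′). With
spot-to-sample-mean expression ratios

```
R5′ = x5′(s) / mean_s x5′      R3′ = x3′(s) / mean_s x3′

C(s) = −R5′   if R5′ ≥ R3′     (fusion absent; level mirrors 5′ gene)
C(s) = +R3′   otherwise        (fusion present; level mirrors fusion)
```

positive C-scores localise the fusion in the section; an optional
pseudo-count of 1 on dividend and divisor avoids zero divisions. Spots
are labelled occurrence (C > 0) / absence (C < 0, with C = 0 neutral or
absence depending on convention) and graded around ±1
(mild/strong occurrence/absence).

**Diversity index** for screening unknown pairs. For each pair,
C-scores (concatenated over sections, rounded to one decimal) give
`D = N × U` with `N` the number of nonzero scores and `U` the number of
distinct nonzero scores; genuinely fused pairs are far more dispersed
than random pairs and rank at the top. Candidate cis-SAGe pairs can be
restricted to same-strand genes within 30 kbp from a GTF.

**Poly(A) mechanism classifier.** Given per-gene tail counts (e.g. from
TAIL-seq), a pair with no 5′ tails but 3′ tails shows the
`fusion_pattern` (cis-SAGe or genomic fusion — indistinguishable by
tails alone); tails on both genes show the `trans_splicing_pattern`;
no 3′ tails is `undetected`.

Downstream, occurrence and absence spots are compared by fold change +
two-sample t-test (Welch default) with Benjamini–Hochberg FDR, C-score
maps are correlated (Pearson/Spearman) with transcriptomic-factor
activity maps, and per-grade spot fractions are summarised inside
factor-active areas. A negative-binomial synthetic-tissue generator
with radial factors and planted fusion events makes the whole pipeline
testable without any external download.

## Worked example

```python
import stfusion as sf
from stfusion.datasets import HELA_FUSION_PAIRS, HELA_TAIL_COUNTS

# 1. mechanism calls from published HeLa poly(A)-tail counts
for p in sf.classify_table(list(HELA_FUSION_PAIRS), HELA_TAIL_COUNTS):
    print(f"{p.gene5}-{p.gene3}: tails {p.count5}/{p.count3} -> {p.call}")

# 2. localise a planted fusion in a synthetic section
cfg = sf.SyntheticConfig(seed=1)
counts, factors, truth = sf.simulate_tissue(cfg)
cs = sf.cscore_map(counts, cfg.pair)
print(sf.evaluate_recovery(cs, truth))
corr = sf.correlate_factor(cs, factors, "Cancer")
print(f"Pearson rho vs cancer activity: {corr.rho_pearson:.2f} "
      f"(p = {corr.p_pearson:.2e}, n = {corr.n_spots})")
```

prints

```
FOXRED2-TXN2: tails 0/340 -> fusion_pattern
LHX6-NDUFA8: tails 0/218 -> fusion_pattern
SLC2A11-MIF: tails 0/842 -> fusion_pattern
SLC45A3-ELK4: tails 0/5 -> fusion_pattern
TXNDC9-LYG1: tails 10/30 -> trans_splicing_pattern
UBE2Q2-FBXO22: tails 0/97 -> fusion_pattern
{'sensitivity': 1.0, 'specificity': 0.967849223946785, 'n_fusion_spots': 121, 'n_other_spots': 902}
Pearson rho vs cancer activity: 0.83 (p = 3.29e-265, n = 1023)
```

Five of the six confirmed cis-SAGe/gene-fusion pairs show the expected
tail pattern; `TXNDC9-LYG1` reads as trans-splicing because a large
genomic inversion (not trans-splicing) left both parents polyadenylated.
On the synthetic section every planted fusion spot is called occurrence,
96.8% of the other spots are called absence/neutral, and the C-score map
correlates strongly with the cancer factor's activity map in which the
fusion was planted.

The same steps are available from the shell:

```
stfusion --seed 1 simulate --out-prefix sim_
stfusion cscore --counts sim_counts.tsv --pair SLC45A3,ELK4 \
    --plot map.png --out cscores.tsv
stfusion correlate --cscores cscores.tsv --factors sim_factors.tsv \
    --factor Cancer --out corr.tsv
stfusion de --counts sim_counts.tsv --cscores cscores.tsv --out de.tsv
```

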