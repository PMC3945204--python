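# funcbind

Most transcription-factor (TF) binding near a gene has no measurable effect
on that gene's expression. `funcbind` quantifies this: given a siRNA
knockdown screen read out on expression arrays and genome-wide binding maps
(ChIP-style peaks plus DNase-footprint sites with occupancy posteriors), it
classifies each binding event as *functional* — the bound gene is
differentially expressed when the binding factor is knocked down — and
characterizes where functional binding lives (chromatin state, motif
strength, distance to the TSS, co-occupancy).

The package is organized as an analysis project: a library under
`src/funcbind/` holding every computation, numbered drivers under
`analysis/` that run the study stage by stage, and a ground-truthed
synthetic-study generator that backs the test suite.

## The model

**Normalization.** Probes are filtered (unique mapping, no 1-mismatch
secondary hit, not on chrY, no heterozygous SNP; 3′-most probe per gene),
log2 intensities are quantile normalized across all arrays together, and
hidden nuisance factors are removed with a control-gene factor adjustment:
the *k* leading array-side singular vectors **W** of the row-centered
control-probe submatrix are estimated from the least-variable probes per
transfection batch (lists intersected across batches), and every gene's row
is replaced by its mean plus the residual after regressing on **W**. The
number of factors *k* is chosen by a replicate-concordance diagnostic:
the smallest *k* with zero differentially expressed genes between control
groups across batches whose replicated-knockdown concordance is within
counting noise of the maximum.

**Differential expression.** For each gene *i* on array *j*,

    Y_ij = mu_i + beta_j X_i + eps_ij

with `beta_j` the knockdown/control indicator and `X_i` the knockdown
effect (log2). The likelihood-ratio statistic for `X_i = 0` is
`n·ln(RSS0/RSS1)`; p-values use the exact F reference by default (the
asymptotic chi-square(1) reference is available via `lrt_dist="chi2"`).
Multiple testing uses Storey q-values (pi0 estimated on a lambda grid with
a cubic smoother). The knockdown efficiency of the targeted transcript is
`(1 − 2^log2fc)·100`.

**Binding and integration.** One reference TSS per gene (highest CAGE
score, ties resolved to the floor midpoint), footprint sites filtered at
posterior > 0.95, all records unified per factor and reduced to interval
midpoints. A gene is *bound* when an event midpoint lies within 10 kb of
its reference TSS (inclusive; a promoter-excluded annulus and
distal-element links are also supported), and *functional binding* is
bound ∧ differentially expressed (q ≤ 0.05). Downstream statistics:
Fisher's exact test on the bound × DE table, relative enrichment
`a·N/((a+b)(a+c))`, per-chromatin-state Fisher tests with
Benjamini–Hochberg adjustment, Wilcoxon rank-sum comparisons of site
features, co-occupancy enrichment binned by the Jaccard fraction of shared
DE factors, and the fraction of up-regulated targets.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 1     # fixtures -> scratch/study
python analysis/02_normalize_and_choose_k.py
python analysis/03_differential_expression.py
python analysis/04_binding_maps.py
python analysis/05_functional_binding.py
python analysis/06_window_sensitivity.py
```

which prints, among other things:

```
selected k = 4 (control-group DE zero, replicate concordance maximal)
PC1 batch-association p: 4.81e-55 before adjustment, 0.92 after
DE genes at FDR 5%: 8-22 (median 14)
array-based knockdown efficiency: 54-87%
median |efficiency error| vs planted truth: 1.8 percentage points
fraction of bound genes that are DE: median 5.4% (i.e. 94.6% of direct
  binding is non-functional)
overlap significant (Fisher p<0.05) in 13/14 experiments; mean relative
  enrichment 13.16
strong-enhancer binding near DE genes (pooled): OR 2.63, BH-adjusted p 2.4e-05
direction of effect: mean 46.9% of DE genes up-regulated after knockdown
```

Read: the batch structure planted by the generator (three transfection
rounds) dominates the unadjusted arrays and is fully removed at the
diagnostically chosen k; knockdowns are recovered from the arrays to within
a couple of percentage points; binding and differential expression overlap
far more than chance (Fisher), yet the overwhelming majority of binding
events sit next to genes that do not respond — and the binding that *is*
functional is enriched in strong-enhancer chromatin. The same two commands
are available as a CLI (`funcbind simulate`, `funcbind analyze`).

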