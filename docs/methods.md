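# Methods

## The analysis

The pipeline asks one question of a knockdown screen: which TF–DNA binding
events are *functional*, in the operational sense that the bound gene's
expression changes when the binding factor is depleted. The chain is

1. probe filtering → quantile normalization → control-gene factor removal;
2. per-gene likelihood-ratio tests of knockdown vs control, Storey q-values;
3. binding maps: reference-TSS choice, posterior filtering, midpoint
   unification, TSS-window (or distal-link) assignment;
4. integration: functional classification and the comparisons built on it.

Assumptions worth stating. The expression model is a fixed-effect Gaussian
two-group comparison per gene with a shared error variance; arrays are
treated as exchangeable after the factor adjustment. The factor adjustment
assumes the unwanted variation is low-rank with loadings spread over all
genes and that the control probes (least variable per batch, intersected
across batches) carry no knockdown signal. Binding assignment assumes a
single reference TSS per gene adequately anchors regulatory distance, and
the window predicate is symmetric and strand-free.

## Statistical choices

**LRT reference distribution.** The statistic `n·ln(RSS0/RSS1)` is a
monotone transform of the exact F statistic, so gene rankings are identical
under either reference. The pipeline default is the exact F
(`SimConfig.lrt_dist = "f"`): at the design's array counts (3 knockdown
arrays vs 18 controls) the chi-square(1) reference is sharply
anti-conservative exactly where q-value calls are decided — in the extreme
tail — and in combination with averaged controls it produced ~90% false
discovery proportions in simulation. The chi-square reference remains
available (`lrt_dist="chi2"`) and is the default of the low-level
`lrt_gene`/`lrt_matrix` functions.

**Control arrays in the DE comparison.** Averaging matched control arrays
across batches into six pooled profiles (`pool_controls_de=True`) shrinks
the control group's variance threefold while the equal-variance model
assumes none of that, and caps the error degrees of freedom at 7. The
default therefore tests the three knockdown arrays against all un-averaged
control arrays (df = 19); the averaging path is implemented and one flag
away.

**Knockdown efficiency** is estimated against *same-batch* controls.
Residualizing a gene's row on the factor scores absorbs the component of
the knockdown signature that lies in the batch subspace (about 10% of the
log2 effect at this study size, since the three knockdown arrays sit inside
one batch); within-batch contrasts are exactly invariant to that
absorption, cross-batch contrasts are not. DE testing still uses all
controls — for null genes the absorption has no effect.

**Choosing k.** For each candidate k the diagnostic computes (a) DE genes
between control groups across batches at FDR 5%, (b) DE genes shared within
replicated knockdown pairs, and (c) the correlation of −log10 p between
replicated pairs. Selection: among k with (a) = 0, the smallest k whose (b)
is within `sqrt(max b)` of the maximum — (b) is a small count, and a plain
argmax chases Poisson noise into too-large k. Criterion (a) excludes the
siRNA-targeted transcripts (their knockdown dip makes residualization
displace their control arrays at every k — they are perturbation signal,
not unwanted variation) and runs on detection-passing genes only (quantile
normalization pins sub-detection rows to near-constant values whose tiny
variances produce degenerate tests).

**Degenerate genes.** `RSS1 = 0` with a group difference is perfect
separation: the statistic is set to +∞, p to the smallest representable
value, and the gene is flagged, never dropped. An all-constant row
(`RSS0 = RSS1 = 0`) carries no evidence and gets p = 1.

**Storey pi0** is estimated on the lambda grid 0, 0.05, …, 0.90 by a
least-squares cubic fit evaluated at λ = 0.90, clamped to [1/m, 1]. The
q-value is the usual step-up `π0·min_{p_(j)≥p_(i)} p_(j)·m/j`.

**Fisher's exact test** (two-sided, conditional on margins) is delegated
to scipy, which we verified agrees with full exact-rational hypergeometric
enumeration to < 1e-12 on every 2×2 table with N ≤ 30. The odds ratio gets
a 0.5 continuity correction when a cell is zero — reporting only, never
the p-value. Rank-sum comparisons use exact enumeration when both groups
have ≤ 8 observations and the tie-corrected normal approximation with
continuity correction otherwise.

**Coordinates.** All interval files are 0-based half-open; midpoints are
`floor((start+end)/2)`; the window predicate is inclusive
(`|midpoint − TSS| ≤ w`), the promoter-exclusion radius strict
(`distance > inner`); the footprint posterior threshold is strict
(`> 0.95`). Distances are absolute, so strand affects only which TSS is
chosen, never the window arithmetic. The log-distance transform is
`log10(d_kb + 0.001)` on the kb scale (a bp-scale variant is flagged).

**Chromatin-state test.** The unit is the binding event (not the gene):
each event inherits the DE status of its assigned gene(s) — "DE" if any
assigned gene is DE — and the per-state 2×2 (event in state × gene DE) is
tested by Fisher with BH adjustment across the 12 states within an
experiment; no correction across experiments.

**Co-occupancy.** The literature does not pin a formula for "enrichment
for functional co-occupancy"; ours is: for each experiment pair, the
relative enrichment of (gene DE in both) × (gene bound by ≥1 factor in the
intersection of the two DE-factor sets) over genes expressed in both,
binned by the Jaccard fraction of shared DE factors. It is isolated in one
function so it can be swapped.

**Effect size.** `effect_pct = (2^|log2fc| − 1)·100` (symmetric on the log
scale; a halving and a doubling both read 100%). The asymmetric
alternative `(1 − 2^−|log2fc|)·100` is available via `symmetric=False`.

## The synthetic study

The generator emulates the statistical structure the analysis assumes; it
is the only data source the tests use. Defaults (all in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| n_genes / n_tfs / n_knockdowns | 4000 / 30 / 12 | scaled-down study (the real screen is ~8,900 genes, 59 knockdowns) |
| n_batches × controls_per_batch | 3 × 6 | transfection rounds; 18 control arrays |
| replicates_per_kd, n_repeated | 3, 2 | triplicates; two knockdowns repeated in a second batch |
| kd_efficiency_range | 0.5–0.9 | planted knockdown efficiencies |
| median_effect_pct | 10 | median \|fold change − 1\| among true targets; magnitudes are exponential, so the median is exact by construction |
| mean_out_degree | 150 | bound genes per factor |
| functional_fraction | 0.2 | fraction of bound genes that are true targets |
| mean_unbound_targets | 45 | regulated-but-unbound (indirect) targets per knocked factor |
| tf_module_size / module_target_overlap / module_tf_coupling | 4 / 0.5 / 0.6 | co-regulated TF modules sharing a target pool |
| k_true / batch_factor_sd / array_jitter_sd / loading_sd | 3 / 1.0 / 0.1 / 0.3 | unwanted factors: batch-level means plus small per-array jitter, Gaussian loadings on every gene |
| noise_sd | 0.10 | residual per-cell log2 noise (typical replicate noise for bead arrays; small enough that ≥30% shifts are detectable from a triplicate at study-wide FDR 5%) |
| baseline_mean / sd | 8 / 1.5 | gene log2 baselines; TF baselines are floored so targeted transcripts stay detectable, as in a screen that targets expressed factors |
| enhancer_enrichment / motif_shift / cons_shift | 5 / 0.5 / 0 | placement weight for functional sites in strong-enhancer segments; motif-score increment at functional sites; no conservation shift |
| detection_tau / detection_s | 4.8 / 0.25 | logistic detection-p curve; ~85–95% of genes pass the detection filter |
| gene_spacing | 100 kb | one synthetic chromosome, non-overlapping windows |

Genome layout: gene neighborhoods (±30 kb) are finely tiled with
chromatin-state segments — promoter states in the ±1 kb core, the other
nine states outside, strong enhancers at weight 0.18 — separated by broad
filler segments. Site placement draws from a promoter-concentrated base
distribution (70% tight around the anchor, 30% uniform within ±9.6 kb);
functional sites are chosen among 12 such candidates with weight
`enhancer_enrichment` on strong-enhancer candidates, which reduces exactly
to decoy placement when the weight is 1 and puts ~20% of functional sites
in strong enhancers at the default weight (decoys ~5%). Sub-threshold
background footprints (posterior ≤ 0.95) are added so the posterior filter
does real work.

Network: TFs are grouped into modules sharing a target pool (which
includes the module's own TFs), planting co-occupancy and downstream-DE
structure; regulated-but-unbound targets are drawn *independently* of the
bound set, so a decoy-bound gene can be independently regulated — that is
what independence means, and such chance overlaps are deliberately not
flagged functional. With `functional_fraction=0` **and** `tf_module_size=1`
binding is fully independent of regulation: that is the null-integration
configuration (with modules on, the shared pool is a real planted
dependence).

Expression: observed log2 intensity = gene baseline + probe offset +
planted knockdown delta (the targeted TF gets `log2(1 − κ)`; regulated
targets their planted effects; targets-of-regulated-TFs an attenuated
second step, scale `indirect_attenuation·δ_TF/log2(1 − mean κ)`) +
loadings·factor scores + N(0, noise_sd). Detection p is a deterministic
logistic function of the observed intensity. Every stage uses its own
substream of the config seed, so the whole study is a pure function of the
configuration.

### What the generator does *not* emulate

Heteroscedastic gene variances (all genes share `noise_sd`, which is why
the control-probe intersection is smaller than a real study's — real
variance rankings correlate strongly across batches); probe chemistry and
background correction; read-level binding data; genuine regulatory
cascades deeper than one step; genome sequence. Tests passing on this
generator show the *operations* are correct and that the pipeline recovers
structure of the planted kind at the planted magnitudes — not that the
biology of any real dataset matches those magnitudes.

The planted-structure and null-integration acceptance checks (strong-
enhancer enrichment, motif/conservation shifts, co-occupancy trend, null
relative enrichment) are run against the generator's truth tables — the
planted regulated-target sets stand in for DE calls. This isolates the
annotation structure and the detection operations from DE power, which at
desk scale (12 knockdowns, ~3,500 expressed genes, median 10% effects) is
deliberately low, exactly as in the real screen. The pipeline-level
versions of the same quantities, with noisy DE calls, are what the
`analysis/` drivers print.

## Problem sizes used by the tests

Unit and property tests simulate studies of 300–1,000 genes with 6–16
knockdowns; the acceptance checks use 50 seeds for calibration/recovery
Monte-Carlos, 30 seeds for the planted-structure arms, and the default
4,000-gene study (two seeds) for efficiency and sensitivity recovery. The
full suite runs in roughly five minutes on one core.

## Known limitations

* The factor adjustment attenuates within-one-batch biological contrasts
  by the overlap of the contrast with the batch subspace (~10% here);
  efficiency estimation sidesteps it, DE effect sizes do not.
* The replicate-concordance criterion (b) is a small count; its peak
  location is noisy, hence the noise-margin selection rule.
* `relative_enrichment` and the co-occupancy statistic are unstable when
  the DE or bound sets are tiny; the drivers report them but small-n
  values should be read with that in mind.
* The distal-link assignment covers only the fraction of events that fall
  inside elements (~1% at the defaults), so its per-experiment overlap
  tables are sparse.
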