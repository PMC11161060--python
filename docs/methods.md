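# Methods

## Problem and model

`markretain` quantifies what happens when an active chromatin mark
(H3K4me3) is suppressed genome-wide between two conditions while a
repressive mark (H3K27me3) stays put, and whether gene-specific
*retention* of the active mark carries forward into later gene
expression. The analysis has four layers: a deterministic signal chain on
binned coverage, per-gene statistics, subset-vs-bulk resampling
inference, and cross-stage linkage. A matched synthetic-data generator
provides seeded datasets with known ground truth.

## Signal chain

Raw binned coverage is processed per sample (one mark in one condition):

1. **Smoothing.** Centred moving-window average, default 100 bp. The
   window must be a whole number of bins; at chromosome edges it
   truncates and the mean is renormalized over the bins actually present,
   so no signal is invented beyond the data. On H3K27me3 tracks binned at
   1,000 bp a 100 bp window is not representable and the effective window
   falls back to one bin (a no-op).
2. **Global percentile normalization.** Each bin value is replaced by
   `100·(rank − ½)/N`, ranking over *all* bins of *all* chromosomes of
   the sample with average ranks for ties. This formula maps a constant
   track to 50, is idempotent, preserves rank order exactly, and removes
   all scale information between samples (sequencing depth, IP
   efficiency).
3. **Background threshold.** Bins below the global 95th-percentile cutoff
   are set to zero. The cutoff is the smallest observed value at or above
   the requested quantile (`numpy` quantile, method `higher`) and ties at
   the cutoff are *kept*; for distinct percentile-normalized values this
   keeps exactly `ceil(0.05·N)` bins. Quantile 0 is allowed (with a
   warning) and keeps everything.

**Where rank normalization is appropriate — a deliberate split.** Rank
normalization erases any genome-wide multiplicative factor by
construction: a uniform 2-fold suppression leaves every percentile
unchanged. It is therefore used for *within-sample* operations —
background thresholding, decile selection, and the ±2 SD per-bin
difference classification, where the percentile scale makes the two
samples comparable. Cross-condition *ratio* statistics (retention, the
K4/K27 ratio change) are computed from smoothed, scale-preserving
aggregated signal, where the synthetic tracks are depth-matched by
construction and a global suppression factor is exactly the quantity of
interest. The pipeline exposes this as `processing.normalize`; with real
tracks of unequal depth a user should either depth-match externally or
interpret raw-scale ratios with care.

## Gene-level statistics

- **Aggregation** sums bin values over the gene body; a bin belongs to a
  gene when its *midpoint* lies in `[start, end)` (no double counting
  between adjacent genes; strand ignored; no promoter flank — flank size
  is configuration, default 0). Tests keep a brute-force per-bin oracle
  for this rule.
- **Detectability.** A gene is detectable when its control H3K4me3 level
  exceeds a floor (default 0 after aggregation). Ratio and retention are
  undefined (NaN) for non-detectable genes, which are excluded from all
  summaries — exclusion, not a pseudocount, is the rule for retention.
- **Mark ratio** `K4/K27` uses a pseudocount (default 1 normalized unit)
  only when the denominator is exactly 0; `K4 = 0` gives ratio 0.
- **Retention** is the plain ratio `K4_treated/K4_control`.
- **±k SD classification** works on per-bin differences of
  percentile-normalized values; mean and SD (population SD, ddof = 0) are
  taken over all bins including any outliers. Zero variance classifies
  everything as `within`, with a warning. Adding a constant to both
  tracks does not change the classification.
- **Extreme deciles**: set size is `round(f·n_detectable)` (half-up);
  boundary ties are resolved by ascending gene ID, deterministically,
  with a warning when the tie bites.
- **Differential filter**: strictly `fc > 1.5` (or `< 1/1.5`) *and*
  `p < 0.05`; boundary values are excluded on both axes.
- **qPCR**: `fold = 2^−ΔΔCt` with
  `ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control`.

## Subset-vs-bulk inference

The **bootstrap median test** draws, in each of `n_iter` cycles
(default 1,000,000), `|S|` genes *without replacement* from the full
population — subset members are not excluded from the pool, because the
null is "a random selection from all genes" — and compares the null
median to the observed subset median. Both one-sided tail probabilities
are reported with add-one smoothing, `p = (count + 1)/(n_iter + 1)`, so
p = 0 cannot occur and ties between a null median and the observed median
count toward *both* tails (conservative). The reported direction is the
smaller tail; callers wanting a two-sided p can double the smaller tail.
Across many subset queries in one report, Benjamini–Hochberg adjustment
is applied. Sampling is vectorized (random sort keys + `argpartition`) in
memory-bounded chunks and fully determined by the seed.

`exact_median_test` enumerates all `C(N, k)` selections (refusing beyond
10⁶) and is the oracle the bootstrap is verified against.

**Gene-set overlap** uses the upper-tail hypergeometric law
(`scipy.stats.hypergeom.sf`), equivalent to a one-sided Fisher exact
test and symmetric in the two sets; the test-suite oracle enumerates all
draws for universes up to 12 genes.

**CDF shifts** report right-continuous empirical CDFs of subset and bulk
on the shared value grid, the median difference and the KS distance,
with the bootstrap median test attached for significance.

**Protein subsets** get a median fold-change and a bootstrap SE (SD of
the median over 1,000 within-subset resamples with replacement). A
median has no closed-form SE; the bootstrap SE is used and labelled as
such. Subsets smaller than 3 are flagged unreliable.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the
reference study conditions used by the acceptance checks:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 1000 | genes packed into the genome |
| `genome_length` | 6 Mb | split over `n_chromosomes` = 2 |
| `gene_length_mean/sd` | 2,000 / 400 bp | typical fly gene scale |
| `bin_width_k4` / `bin_width_k27` | 100 / 1,000 bp | per-mark resolution |
| `baseline_k4_log_mean/sd` | 3.0 / 1.0 | log-normal per-bin gene signal |
| `suppression_s` | 0.5 | global treated/control K4 factor |
| `subset_fraction` | 0.10 | wing-like share of genes |
| `retention_boost_r` | 1.6 | extra retention of the subset |
| `expression_coupling_rho` | 0.8 | target Spearman, chromatin ↔ expression |
| `retention_jitter_sd` | 0.25 | per-gene log-retention scatter |
| `noise_dispersion` | 0.1 | NB overdispersion (0 = Poisson, None = off) |
| `background_level` | 1.0 | off-gene signal per bin |
| `de_log2_effect` | 1.0 | later-stage up-shift of subset genes |

Genes are placed without overlap (sorted uniform gaps into the leftover
slack; a genome too small for its genes raises a capacity error). Bins
whose midpoint falls in a gene carry the gene's baseline level; all other
bins sit at the background level in *every* track — non-specific
background does not respond to treatment, so in the no-noise limit
per-gene retention equals `s` (times `r` on the subset) exactly, keeping
oracles exact. H3K27me3 expectations are shared between conditions.
Count noise is negative binomial, `var = μ + α·μ²`, drawn per bin;
replicate tracks (optional) are merged by the mean.

Rank couplings use a Gaussian copula with Pearson parameter
`a = 2·sin(π·ρ_s/6)`, the exact inversion of the bivariate-normal
Spearman relation, so achieved rank correlations are unbiased for the
target: retention jitter is coupled to the baseline K4 level (highly
expressed genes retain better), and later-stage expression is coupled to
the realized post-treatment K4. Later-stage tables carry control and
treated replicate columns (3 each, log-normal replicate noise, sd 0.2);
the treated lineage up-shifts wing-like genes by `de_log2_effect` log2
units, which couples subset membership to up-regulation. Protein log2
fold-changes are normal with per-set location shifts given in
`protein_log2_shifts` (a protein in several sets sums their shifts).

Randomness flows through named per-stage streams
(`default_rng([seed, stream_id])`: annotation 0, tracks 1, expression 2,
proteins 3, gene sets 4, latents 5), so identical seeds give
byte-identical text outputs and any stage can be regenerated alone.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artefacts (mappability, GC bias,
fragment-size effects, peak shape), overlapping or nested genes,
non-uniform within-gene mark profiles (promoter-proximal peaks),
chromosome-scale covariance, and replicate-specific IP efficiency.
Recovery results quantify the statistical machinery, not robustness to
those artefacts.

## Pipeline

`run_pipeline` executes simulate (or load) → normalize → aggregate →
subset tests → linkage from one YAML config, writing only plain-text
outputs (bedGraph, BED6, TSV, JSON) plus a manifest with parameters,
per-stage seeds and SHA-256 checksums; identical configs reproduce
identical manifests. One global seed fans out as `seed + stage_index`.
Files are written atomically (temp file + rename). Exit codes in the
CLI: 0 ok, 1 validation error, 2 runtime failure.

## Numerical and design choices

- Direction fractions use strict inequality with an optional *relative*
  tolerance band (default 0 in the library, 0.05 in the pipeline config)
  defining the "unchanged" class; the band is reported in the output.
- Spearman (not Pearson) for retention–expression: expression is
  heavy-tailed and only monotone association is claimed.
- Unpaired gene IDs between tables are dropped with a logged count,
  never imputed; a selection that resolves to nothing is an error.
- The two-group expression test is a Welch t-test on `log2(FPKM + 1)`
  between replicate columns with the fold-change taken on condition
  means — deliberately simple, since differential-expression modelling
  is not this package's contribution.
- Problem sizes in the test suite: oracle comparisons run at up to
  `C(20, 6)` enumerated selections and 10⁵ bootstrap iterations; null
  calibration uses 8,000 replications of a 2,000-iteration test on a
  150-gene population (more replications than strictly needed for the
  0.02 KS band, which sharpens the calibration estimate); parameter
  recovery and direction checks use 20 seeds at the full 1,000-gene
  reference conditions.

## Known limitations

- Percentile-normalized tracks cannot, by construction, express a
  uniform genome-wide suppression; scale-sensitive conclusions from real
  data need depth-matched raw tracks or spike-in scaling (out of scope).
- The bootstrap median test assumes exchangeability of genes under the
  null; correlated genes (e.g. clustered paralogues) would make it
  anti-conservative.
- `exact_median_test` is limited to 10⁶ combinations; beyond that only
  the bootstrap estimate is available.
- The generator's genes never overlap, though the aggregation rule
  tolerates overlap; fractional bin assignment (instead of the midpoint
  rule) is not implemented.
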