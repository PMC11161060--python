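# markretain

Two-condition histone-mark **retention** analysis for ChIP-seq-style
binned coverage data, built around the question: *when an active
chromatin mark is suppressed genome-wide, which genes hold on to it, and
does that early chromatin state predict later gene expression?*

The motivating setting is a *Drosophila* embryo in which an environmental
exposure broadly depletes H3K4me3 (the Trithorax-deposited "active" mark)
while leaving H3K27me3 (the Polycomb-associated "repressive" mark)
essentially unchanged. Wing-development genes retain H3K4me3
preferentially, and genes with high post-exposure H3K4me3 are expressed
at higher levels in a later-stage tissue (the haltere imaginal disc).
`markretain` implements the complete analysis as a reusable, seeded
pipeline, together with a synthetic-data generator that reproduces the
statistical structure of such an experiment so every stage can be tested
without access to sequencing data.

## What it computes

**Signal chain** (per mark × condition): binned coverage (bedGraph) is
smoothed with a centred 100 bp moving window, rank-transformed by *global
percentile normalization*

```
value_i = 100 · (rank_i − ½) / N        (average ranks for ties)
```

over all bins of all chromosomes, and thresholded at the 95th percentile
to separate signal from background.

**Gene level**: bin values are summed over each gene body (a bin belongs
to a gene when its midpoint falls in `[start, end)`), giving per-gene
levels `K4_ctrl, K4_trt, K27_ctrl, K27_trt` and from them

- the mark ratio `K4/K27` per condition,
- the **retention score** `ret(g) = K4_trt(g) / K4_ctrl(g)` for genes
  with detectable control H3K4me3,
- a ±2 SD classification of per-bin treated−control differences,
- top/bottom-decile gene sets by any per-gene metric.

**Subset inference**: a bootstrap median test — repeated cycles (default
1,000,000) of drawing `|S|` genes at random from all genes and counting
how often the random median exceeds or falls below the subset median,
reported as add-one-smoothed tail probabilities
`p_upper = (#{med_null ≥ med_S} + 1)/(n_iter + 1)` — plus exact
enumeration as its small-sample oracle, one-sided hypergeometric
(Fisher-type) gene-set overlap tests, empirical-CDF shift summaries and
per-subset median fold-changes with bootstrap SEs.

**Linkage**: fractions of genes whose K4/K27 ratio moved down/up between
conditions, expression of extreme chromatin deciles, the Spearman
correlation between retention and expression, and enrichment of target
gene sets among differentially expressed genes (fold-change > 1.5,
p < 0.05; BH-corrected within each report).

## Worked example

```python
import markretain as mr

params = mr.SimulationParams(seed=1)          # 1,000 genes, s=0.5, r=1.6
data = mr.simulate_dataset(params)

levels = {k: mr.aggregate_gene_signal(t, data.annotation)
          for k, t in data.tracks.items()}
table = mr.build_gene_table(levels["k4_ctrl"], levels["k4_treated"],
                            levels["k27_ctrl"], levels["k27_treated"])
ret = table.loc[table.detectable, "retention"]

print(round(ret.median(), 3))                 # 0.522
print(round(ret.loc[data.subset].median(), 3))  # 0.838

res = mr.bootstrap_median_test(ret, data.subset, n_iter=100_000, seed=2)
print(res.direction, res.p_upper)             # higher 9.99990000099999e-06
```

The bulk median retention (0.522) recovers the simulated genome-wide
suppression factor 0.5; the wing-like subset median (0.838) reflects its
1.6× retention boost, and the bootstrap test calls the subset shift
`higher` at the smallest p-value representable with 10⁵ iterations (the
add-one floor `1/(n_iter+1)`).

The same analysis runs end to end from a YAML config:

```bash
markretain run --config examples/sim.yaml --out out/
```

writing bedGraph tracks, the per-gene table, subset-test and linkage
reports, and a manifest with seeds and SHA-256 checksums (identical
configs reproduce byte-identical outputs).

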