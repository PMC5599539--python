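# paleoclock

Fossil-calibrated relaxed-clock divergence dating and lineage-rate comparison
for partitioned multi-gene nucleotide alignments.

`paleoclock` is built around the workflow used to date shallow marine
radiations against the fossil record — the motivating system is the New World
sand dollars (*Encope*, *Mellita*, *Lanthonia*), where clades split by the
rising Central American Isthmus carry fossils at multiple nodes and the
mitochondrial clock turns out to run an order of magnitude slower in one
genus than in its close relatives. The package provides, as a tested
library plus a thin CLI:

- **Alignment handling** — FASTA I/O, ambiguous-end trimming, haplotype
  collapsing, multi-gene concatenation with a partition map.
- **Substitution models** — the GTR family expressed through six-digit
  exchangeability class-strings (`HKY = 010010`, `TrN = 010020`,
  `TIM3 = 012032`, arbitrary strings such as `001120`), with discrete-gamma
  rate heterogeneity and invariant sites; Q is normalized to one expected
  substitution per site per unit branch length.
- **Pruning likelihood** — partitioned Felsenstein pruning over compressed
  site patterns with per-node rescaling (numba-compiled), plus a brute-force
  enumeration oracle for small trees.
- **Relaxed-clock MCMC** — Metropolis–Hastings over node ages on a fixed
  rooted topology under an uncorrelated lognormal clock (per-partition
  `ucld.mean`, `ucld.stdev`, per-branch rates). Fossil calibrations enter as
  exponential priors offset at the fossil's minimum age with the mean chosen
  so the prior's 95th percentile sits at twice the fossil age
  (`mean = offset / ln 20`). Multi-run combining, burn-in removal, thinning,
  95% HPD intervals and ESS diagnostics included.
- **Calibration jackknife** — leave-one-fossil-out re-dating with per-node
  flags for medians falling outside the full-run HPDs.
- **Distances and rates** — Tamura–Nei (TN93) distances with gamma
  correction, pooled over all pairs between clades (composite-likelihood
  style); divergence rate = percent distance / split age (%/My); per-gene
  medians, bias-bounded rate intervals, fold ratios between lineages, and a
  Spearman rank correlation of rate against age (exact permutation p for
  n ≤ 9).
- **Synthetic data** — dated-tree simulation (a canonical eight-taxon
  mellitid demonstration shape and conditioned Yule draws), lognormal branch
  rates with clade-specific means, forward sequence simulation under the
  +I+G models, and a complete "two-genus" bundle with a 10× mitochondrial
  rate contrast.
- **Reference tables** — the published divergence/age/rate tables for the
  two sand-dollar genera ship as a packaged fixture
  (`paleoclock.reference_tables`), so the rate arithmetic can be checked
  against printed values.

## Worked example

Simulate the two-genus bundle (two eight-taxon clades with identical dated
topologies; mitochondrial partitions of genus B evolve 10× faster), then
date each genus against its own fossil-style calibrations and compare
per-gene median rates:

```bash
paleoclock simulate --seed 1 --out bundle --sites 1000
paleoclock foldratio --config bundle/run_config.toml --seed 1 \
    --chain-length 40000 --out fold
```

which prints (about half a minute on one core):

```
            A        B
gene
16S      0.63  1268.03
COI      0.31     1.18
ATPase8  0.42     4.65
ATPase6  0.54     2.12
28S      0.01     0.01
median mitochondrial fold ratio: 7.50
```

Rates are in %/My (percent distance per million years). Genus A's rates sit
near the slow published medians; genus B's per-gene folds scatter widely —
the 16S column explodes because the gamma correction at shape α = 0.024 is
extremely saturation-sensitive, while COI/ATPase6 are biased low by
invariant-site saturation — so the cross-gene median (7.50 here, truth 10)
is the robust summary. The truth is in `bundle/truth_rates.tsv`.

The packaged published tables reproduce exactly:

```bash
paleoclock ratetable --fixture encope
```

ends with the per-gene median rates recomputed from the table rows,

```
concatenated  16S   COI   ATPase8  ATPase6  28S
0.32          0.26  0.32  0.49     0.64     0.01
```

matching the printed median row, and every rate cell equals its distance
divided by its age after 2-decimal rounding. The analogous
`--fixture mellita_lanthonia` medians (3.58, 2.32, 5.12, 0.03) give
mitochondrial fold ratios of 16.0 (COI) and 13.8 (16S) against the slow
genus — the "ten times slower" contrast.

Other subcommands: `loglik` (one deterministic partitioned likelihood
evaluation), `date` (full relaxed-clock dating with trace, node-age table
and dated Newick output), `jackknife`, `distances`, `ratetable --config`
(rate table from your own data and ages). Every run writes a
`provenance.json` with the config hash and seed.

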