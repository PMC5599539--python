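# Methods

This note documents the models, priors, numerical choices and limitations of
`paleoclock`. Everything stated here is computed by the test suite or the
acceptance script; nothing is asserted beyond what those runs measure.

## Substitution models

All models are time-reversible GTR-family models specified by a six-digit
exchangeability class-string over the pair order (AC, AG, AT, CG, CT, GT);
pairs sharing a digit share one exchangeability parameter and the first
class is fixed to 1. Named models are aliases (HKY = `010010`,
TrN = `010020`, TIM3 = `012032`, GTR = `012345`, ...), so κ-parameterized
HKY/TrN pass through the same constructor with both transition classes set
to κ. The `001120` model used for the nuclear partition is taken literally
as three rate classes; the description of that model as having "five rates"
elsewhere is not representable by the string and the string wins.

Q is built as S·diag(π) with zero row sums and scaled so
−Σᵢ πᵢQᵢᵢ = 1: branch lengths are expected substitutions per site at
stationarity. P(t) comes from the symmetrized spectral decomposition
(D^{1/2} Q D^{−1/2} is symmetric for reversible Q), with negative roundoff
clipped, rows renormalized, and t = 0 snapped to the exact identity so
zero-length branches with conflicting tips yield a flagged −∞ rather than
roundoff noise.

Across-site rate variation uses the discrete-gamma approximation with
equal-weight quantile categories, each category at the conditional mean of
its Gamma(α, 1/α) segment (computed from the Gamma(α+1) CDF), default four
categories. The invariant class has rate 0 and weight I; gamma rates are
rescaled by 1/(1−I) so the full mixture has mean exactly 1. Normalization
therefore excludes the invariant class from Q's scaling — the standard +I+G
identifiability convention. `+F` means empirical frequencies by counting
(ambiguities excluded).

## Likelihood

Partitioned Felsenstein pruning over compressed site patterns. IUPAC
ambiguity codes become 4-bit state masks; `N` and `-` are full uncertainty.
Per-node rescaling with per-category log accumulators is always on — the
16S-style shape α = 0.024 produces category rates around 10⁻⁵⁰, where
unscaled partials underflow immediately. The inner loop is numba-compiled;
a pure-Python brute-force enumeration over ancestral states (≤ 6 tips)
serves as an independent oracle and agrees to < 10⁻⁹ on random instances.

## Time trees and the relaxed clock

Trees are rooted, strictly bifurcating, ultrametric, with node ages in Ma
and extant tips at 0; polytomies are rejected. A branch's expected
divergence is duration × rate (substitutions/site/My).

Branch rates are continuous i.i.d. lognormal draws per partition:
`ucld.mean` is the real-space mean and `ucld.stdev` the log-space standard
deviation (μ = ln mean − stdev²/2). This is the uncorrelated-lognormal
clock in its continuous form rather than a discretized rate-category
version — the same target, with a simpler sampler.

Priors:

- each fossil calibration is an exponential on its clade's MRCA age, offset
  at the fossil's minimum age, with mean = offset/ln 20 so the 95th prior
  percentile is twice the fossil age (solving offset + mean·ln 20 =
  2·offset); configurable per calibration;
- `ucld.mean` uniform on [0.001, 10¹⁰⁰] by default (the study-style bound;
  synthetic configs with slower truths widen it), `ucld.stdev` exponential
  with mean 0.333;
- node ages otherwise uniform subject to parent-older-than-child ordering
  and a configurable root-age cap. The tree-process prior is deliberately
  the weakest assumption; absolute synthetic dates can differ slightly from
  what a Yule/birth-death prior would give.

Calibration clades must be exactly monophyletic in the fixed topology
(checked at startup). A starting tree violating an offset is inflated with
a warning.

## The MCMC sampler

Metropolis–Hastings with fixed step sizes and explicit Jacobians:

- node-age moves: full uniform redraws within the (parent, children) window
  and small reflected steps within it (both symmetric);
- root-age scaling;
- global and subtree-local rate–time rescaling (ages × c, compensating
  rates ÷ c). The local variant changes only the subtree's stem branch
  length, letting one clade trade rate against time without disturbing the
  rest of the tree;
- per-partition `ucld.mean` scaling, alone and jointly with all of its
  branch rates; `ucld.stdev` scaling; single-branch and subtree-level
  branch-rate scaling.

Correctness is validated three ways: the logged acceptance ratio is
recomputed from independent density evaluations on every proposal of an
instrumented run; prior-only chains reproduce each calibration's
offset-exponential (Kolmogorov–Smirnov distance < 0.05 at 10⁴ samples, on a
tree where every internal node is calibrated — with uncalibrated nodes the
uniform-ordering tree prior legitimately tilts the marginals); and
simulate-then-date replicates cover the true root age (20/20 at the default
conditions, ≥ 17/20 required).

A window of 2000 consecutive rejections triggers a tuning-failure warning.
Chains are seeded (`default_rng([seed, run_id])`); everything downstream is
byte-reproducible. Desk-scale defaults are 10⁵-step chains on 10–20 tips;
study-scale 10⁸-step runs are configuration-reachable, not defaults.

Trace handling mirrors the usual workflow: independent runs, per-run
removal of the first 10% of samples, concatenation, optional regular
thinning. HPD intervals are the shortest contiguous sample window holding
⌈level·n⌉ points (ties to the earliest window, with a floating-point
tolerance); ESS uses Geyer's initial-positive-sequence rule on
FFT-estimated autocorrelations, and a constant column reports NaN rather
than failing.

## Calibration jackknife

For each calibration the dating run is repeated without it (seed offset by
the calibration index; same chain length by default, though the original
workflow used 10× longer reduced runs), and each node's reduced-run median
is flagged against the full-run 95% HPD. A control mode removes nothing
and must flag everything inside. Nodes whose reduced-run HPD more than
doubles are flagged `prior_dominated`.

## Distances and rate statistics

Clade distances are TN93 applied to transition/transversion counts pooled
over every sequence pair in the comparison (a composite-likelihood reading
of "maximum composite likelihood"; a per-pair-average variant is available
and agrees within 5% on homogeneous data). Sites with an ambiguity in
either member of a pair are excluded pairwise; base frequencies are pooled
over compared sites. With a gamma shape α each −ln(w) term becomes
α(w^{−1/α} − 1); the shape defaults to the partition's configured α. A
non-positive log/power argument raises a saturation flag. The estimator
can go slightly negative for near-identical sequences with skewed
frequencies (a known TN93 artifact); tables render such values as 0.00.

Rates are percent distance divided by split age (%/My), printed at two
decimals rounded half away from zero; per-gene medians are computed **on
the rounded per-row rates** (average of the middle two for even counts),
which is what reproduces the published median rows bit-for-bit. Bias
bounds: fastest = upper distance limit / youngest HPD age, slowest = lower
distance limit / oldest HPD age. The Spearman rate-vs-age correlation uses
average ranks and an exact two-sided permutation p for n ≤ 9 (t
approximation above); the published r/p values for this statistic are not
recoverable from the rounded table entries and are not treated as targets.

## Synthetic data

The canonical demonstration tree is the eight-taxon mellitid shape with the
published internal ages (15.15, 9.23, 8.11, 6.77, 5.75, 4.90, 3.88 Ma), so
documentation and tests reference the real system's quantities. Yule draws
conditioned on a root age use i.i.d. truncated-exponential node ages
attached by uniform lineage merging.

The two-genus bundle joins two such clades (identical topology and ages,
root 20 Ma). Per-gene models carry the published shapes/invariant
proportions; exchangeabilities and frequencies are plausible echinoid
values (they are estimated quantities, not printed ones). Slow-genus clock
means are set so distance/age rates land near the published slow-genus
medians (a table rate of r %/My ≈ r/200 subst/site/My per lineage);
mitochondrial partitions of the fast genus are exactly 10× faster, the
nuclear partition equal; `ucld.stdev` = 0.1 within genera. Calibrations sit
at 0.8× the true age (a fossil-younger-than-the-split regime) on the root,
both genus roots and both transisthmian analogue nodes. Default 1000
sites/gene keeps desk-scale runs in minutes; the real gene lengths are a
parameter away. Bundles are byte-identical given a seed.

What the simulator does **not** emulate: indels and alignment error,
within-species sampling (tips are species), fossilized birth–death
placement of calibrations, selection, and base-composition
non-stationarity. Passing recovery tests therefore validates the
machinery, not the robustness of the method to those real-data features.

## The lineage-rate comparison is per-clade by design

A single joint tree under an i.i.d. lognormal clock cannot cheaply
represent a systematic 10× rate contrast between two clades: the posterior
prefers distorting uncalibrated node ages (costing a few
calibration-exponential penalties) over maintaining a bimodal branch-rate
field (costing log-density on every branch). This is a property of the
model, not a sampler failure — likelihood is flat along the rate–time
ridge, and the prior decides. The fold-ratio workflow therefore dates each
clade separately against the calibrations nested inside it — which is also
how fossil-calibrated rate comparisons are constructed in practice, each
lineage's ages coming from its own calibrated analysis — and compares
per-gene median rates across the two runs. At the default conditions the
recovered mitochondrial fold ratio is 6–7.5 against a truth of 10 (within
the [5, 20] acceptance band): per-gene folds scatter in both directions
(invariant-site saturation biases COI/ATPase6 low; the α = 0.024 gamma
correction makes 16S explode under fast rates), exactly as in the real
system, so the cross-gene median is the reported statistic.

## Numerical and engineering choices

- Initial clock means default to a crude JC-corrected distance over twice
  the root age per partition, clamped into the prior support —
  initialization only.
- Internal coordinates are 0-based half-open; all user-facing text is
  1-based inclusive.
- Haplotype collapse uses exact string equality (an `N` never matches a
  base) — the conservative reading of "unique haplotypes".
- End trimming removes only leading/trailing columns containing
  non-base/non-gap symbols; merging of overlapping sequencing fragments is
  assumed already resolved upstream.
- All tabular outputs are TSV with a units header comment; every CLI run
  writes a provenance record (config SHA-256, seed, versions).

## Problem sizes

Default test and acceptance runs use 4–16-tip trees, 400–1000 sites per
partition, and 10⁴–2×10⁵-step chains — sizes chosen so the full validation
suite completes in minutes on one core while keeping every statistical
check at its stated strength (e.g. 20 coverage replicates at 10⁵ steps,
10⁴ prior samples for the KS checks, 100 brute-force likelihood
instances).
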