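"""Pairwise genetic distances and lineage divergence-rate statistics.

Distances use the Tamura-Nei (TN93) estimator with optional gamma rate
correction.  Clade-level "composite" distances pool the transition and
transversion counts over every sequence pair in the comparison before
applying the estimator (a composite-likelihood flavor of the MEGA
"maximum composite likelihood" distance); a per-pair-average variant is
available for comparison.

Rate statistics mirror a fossil-calibrated rate table: per-split rate =
percent distance / split age (%/My), per-gene medians over splits, bias
bounds from distance confidence limits and age HPDs, fold ratios between
lineages, and a Spearman rank correlation of rate against split age.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .alignment import Alignment

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class DistanceError(ValueError):
    """Raised when a distance or rate statistic is undefined."""


class SaturationError(DistanceError):
    """Distance undefined: a logarithm/power argument fell to or below 0."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention), e.g. 0.125 -> 0.13."""
    q = Decimal(1).scaleb(-ndigits)
    # +0.0 normalizes -0.0
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)) + 0.0


@dataclass(frozen=True)
class PairCounts:
    """Pooled sufficient statistics for the TN93 estimator.

    ``n_ag``/``n_ct`` count purine/pyrimidine transitions, ``n_tv``
    transversions, ``n`` the compared sites (summed over pairs), and
    ``base_counts`` the pooled A, C, G, T counts over both members of every
    compared pair.
    """

    n_ag: int
    n_ct: int
    n_tv: int
    n: int
    base_counts: tuple[int, int, int, int]

    def __post_init__(self):
        if min(self.n_ag, self.n_ct, self.n_tv, self.n) < 0:
            raise DistanceError("negative counts")
        if self.n_ag + self.n_ct + self.n_tv > self.n:
            raise DistanceError("difference counts exceed compared sites")

    def __add__(self, other: "PairCounts") -> "PairCounts":
        return PairCounts(
            self.n_ag + other.n_ag,
            self.n_ct + other.n_ct,
            self.n_tv + other.n_tv,
            self.n + other.n,
            tuple(a + b for a, b in zip(self.base_counts, other.base_counts)),
        )

    @property
    def frequencies(self) -> np.ndarray:
        total = sum(self.base_counts)
        if total == 0:
            raise DistanceError("no unambiguous bases in comparison")
        return np.asarray(self.base_counts, dtype=float) / total


def pair_counts(seq_a: str, seq_b: str) -> PairCounts:
    """TN93 counts for one sequence pair; ambiguous sites excluded pairwise."""
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences differ in length")
    n = n_ag = n_ct = n_tv = 0
    bases = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(seq_a, seq_b):
        if x not in bases or y not in bases:
            continue
        n += 1
        bases[x] += 1
        bases[y] += 1
        if x == y:
            continue
        if {x, y} <= PURINES:
            n_ag += 1
        elif {x, y} <= PYRIMIDINES:
            n_ct += 1
        else:
            n_tv += 1
    return PairCounts(
        n_ag, n_ct, n_tv, n, (bases["A"], bases["C"], bases["G"], bases["T"])
    )


def pooled_counts(alignment: Alignment, group_a, group_b) -> PairCounts:
    """Counts pooled over all pairs between (or within) taxon groups.

    With ``group_a == group_b`` (same set) all unordered within-group pairs
    are pooled; otherwise the groups must be disjoint and all cross pairs are
    pooled.
    """
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise DistanceError("empty taxon group")
    if set(a) == set(b):
        pairs = list(itertools.combinations(sorted(set(a)), 2))
        if not pairs:
            raise DistanceError("within-group mode needs at least two taxa")
    elif set(a) & set(b):
        raise DistanceError("groups overlap but are not identical")
    else:
        pairs = [(x, y) for x in a for y in b]
    total = None
    for x, y in pairs:
        c = pair_counts(alignment.row(x), alignment.row(y))
        total = c if total is None else total + c
    if total.n == 0:
        raise DistanceError("no comparable sites in any pair")
    return total


def tn93_gamma_distance(counts: PairCounts, alpha: float | None = None) -> float:
    """TN93 distance (substitutions/site), optionally gamma-corrected.

    With shape ``alpha`` each ``-ln(w)`` term of the TN93 formula is replaced
    by ``alpha * (w**(-1/alpha) - 1)``, the standard gamma transform.  Raises
    :class:`SaturationError` when a log/power argument is non-positive.
    """
    if counts.n == 0:
        raise DistanceError("no compared sites")
    pi = counts.frequencies
    pa, pc, pg, pt = pi
    if np.any(pi <= 0):
        raise DistanceError("all four bases must occur in the comparison")
    pr, py = pa + pg, pc + pt
    p1 = counts.n_ag / counts.n
    p2 = counts.n_ct / counts.n
    q = counts.n_tv / counts.n
    w1 = 1.0 - pr * p1 / (2.0 * pa * pg) - q / (2.0 * pr)
    w2 = 1.0 - py * p2 / (2.0 * pc * pt) - q / (2.0 * py)
    w3 = 1.0 - q / (2.0 * pr * py)
    if min(w1, w2, w3) <= 0.0:
        raise SaturationError("distance undefined (saturation)")
    c1 = 2.0 * pa * pg / pr
    c2 = 2.0 * pc * pt / py
    c3 = 2.0 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)

    if alpha is None:
        def tr(w):
            return -math.log(w)
    else:
        if alpha <= 0:
            raise DistanceError("gamma shape must be positive")

        def tr(w):
            return alpha * (w ** (-1.0 / alpha) - 1.0)

    return c1 * tr(w1) + c2 * tr(w2) + c3 * tr(w3)


def between_clade_distance(
    alignment: Alignment,
    group_a,
    group_b,
    alpha: float | None = None,
    method: str = "pooled",
) -> float:
    """Percent TN93(+gamma) distance between (or within) clades.

    ``method="pooled"`` applies the estimator to counts pooled over all pairs
    (composite likelihood); ``method="average"`` averages per-pair distances.
    """
    if method == "pooled":
        d = tn93_gamma_distance(pooled_counts(alignment, group_a, group_b), alpha)
    elif method == "average":
        a, b = list(group_a), list(group_b)
        if set(a) == set(b):
            pairs = list(itertools.combinations(sorted(set(a)), 2))
        else:
            pairs = [(x, y) for x in a for y in b]
        dists = [
            tn93_gamma_distance(pair_counts(alignment.row(x), alignment.row(y)), alpha)
            for x, y in pairs
        ]
        d = float(np.mean(dists))
    else:
        raise DistanceError(f"unknown method {method!r}")
    return 100.0 * d


def divergence_rate(distance_pct: float, age_ma: float) -> float:
    """Divergence rate in %/My: percent distance / split age, 2-dp rounded
    (half away from zero), matching rate-table presentation."""
    if age_ma <= 0:
        raise DistanceError(f"age must be positive, got {age_ma}")
    return round_half_up(distance_pct / age_ma, 2)


def median_rates(rates) -> float:
    """Median of per-split rates (computed on the 2-dp printed values).

    Uses the average of the two middle values for even counts.
    """
    vals = sorted(round_half_up(r, 2) for r in rates)
    if not vals:
        raise DistanceError("no rates to summarize")
    n = len(vals)
    mid = n // 2
    if n % 2:
        return vals[mid]
    return round_half_up((vals[mid - 1] + vals[mid]) / 2.0, 2)


def bias_bounded_rates(
    dist_ci_pct: tuple[float, float], age_hpd_ma: tuple[float, float]
) -> tuple[float, float]:
    """Fastest/slowest rate bounds from a distance CI and an age HPD.

    fastest = upper distance limit / youngest age; slowest = lower distance
    limit / oldest age.
    """
    d_lo, d_hi = dist_ci_pct
    a_lo, a_hi = age_hpd_ma
    if not (0 <= d_lo <= d_hi):
        raise DistanceError("distance CI must satisfy 0 <= low <= high")
    if not (0 < a_lo <= a_hi):
        raise DistanceError("age HPD must satisfy 0 < low <= high")
    return d_hi / a_lo, d_lo / a_hi


def fold_ratio(rate_a: float, rate_b: float) -> tuple[float, str]:
    """Larger/smaller ratio of two median rates plus which side was faster."""
    if rate_a <= 0 or rate_b <= 0:
        raise DistanceError("rates must be positive for a fold ratio")
    if rate_a >= rate_b:
        return rate_a / rate_b, "first"
    return rate_b / rate_a, "second"


def spearman_rate_age(rates, ages) -> tuple[float, float]:
    """Spearman rank correlation of divergence rate against split age.

    Ties get average ranks; r is the Pearson correlation of the ranks.  The
    p-value is exact (all n! permutations, two-sided) for n <= 9 and a
    t-approximation otherwise.  A constant vector makes r undefined
    (:class:`DistanceError`).
    """
    x = np.asarray(rates, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.size != y.size:
        raise DistanceError("rates and ages differ in length")
    n = x.size
    if n < 3:
        raise DistanceError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DistanceError("correlation undefined for a constant vector")
    rx = rankdata(x)
    ry = rankdata(y)

    def rank_corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    r = rank_corr(rx, ry)
    if n <= 9:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(rank_corr(rx, np.asarray(perm))) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    else:
        t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
        p = min(p, 1.0)
    return r, p
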