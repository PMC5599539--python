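"""Distance estimators and rate statistics against oracles and printed values."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize, stats

from paleoclock.alignment import Alignment
from paleoclock.rates import (
    DistanceError,
    PairCounts,
    SaturationError,
    between_clade_distance,
    bias_bounded_rates,
    divergence_rate,
    fold_ratio,
    median_rates,
    pair_counts,
    pooled_counts,
    round_half_up,
    spearman_rate_age,
    tn93_gamma_distance,
)
from paleoclock.simulate import simulate_alignment
from paleoclock.submodels import make_model
from paleoclock.timetree import TimeTree


class TestPairCounts:
    def test_single_pair_classification(self):
        # A-G purine transition, C-T pyrimidine transition, A-T transversion,
        # two matches, and an N column excluded pairwise
        c = pair_counts("AGCATN", "GGTTTA")
        assert (c.n_ag, c.n_ct, c.n_tv, c.n) == (1, 1, 1, 5)

    def test_pooled_equals_brute_force_sum(self):
        aln = Alignment(
            ("a1", "a2", "a3", "b1", "b2"),
            ("ACGTAC", "ACGTAT", "ACGCAC", "GCGTTC", "GTGTAC"),
        )
        pooled = pooled_counts(aln, ["a1", "a2", "a3"], ["b1", "b2"])
        total = None
        for x, y in itertools.product(["a1", "a2", "a3"], ["b1", "b2"]):
            c = pair_counts(aln.row(x), aln.row(y))
            total = c if total is None else total + c
        assert pooled == total

    def test_single_members_reduce_to_pair(self):
        aln = Alignment(("x", "y"), ("ACGT", "ACGA"))
        assert pooled_counts(aln, ["x"], ["y"]) == pair_counts("ACGT", "ACGA")

    def test_within_clade_identical_sequences(self):
        aln = Alignment(("x", "y", "z"), ("ACGT",) * 3)
        c = pooled_counts(aln, ["x", "y", "z"], ["x", "y", "z"])
        assert c.n_ag == c.n_ct == c.n_tv == 0

    def test_overlapping_groups_rejected(self):
        aln = Alignment(("x", "y", "z"), ("ACGT",) * 3)
        with pytest.raises(DistanceError, match="overlap"):
            pooled_counts(aln, ["x", "y"], ["y", "z"])


class TestTn93Distance:
    def test_identical_sequences_zero(self):
        c = pair_counts("ACGTACGT", "ACGTACGT")
        assert tn93_gamma_distance(c) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("p", [0.03, 0.10, 0.30])
    def test_jc_reduction(self, p):
        n = 60000
        c = PairCounts(
            n_ag=round(n * p / 6), n_ct=round(n * p / 6),
            n_tv=round(n * 2 * p / 3), n=n,
            base_counts=(n // 2, n // 2, n // 2, n // 2),
        )
        p_eff = (c.n_ag + c.n_ct + c.n_tv) / n
        expected = -0.75 * math.log(1 - 4 * p_eff / 3)
        assert tn93_gamma_distance(c) == pytest.approx(expected, abs=1e-10)

    def test_matches_numeric_mle_oracle(self, rng):
        """Closed form equals a numeric ML fit of the reduced multinomial."""
        tree = TimeTree.build(("x", "y", 1.0))
        model = make_model("TrN", class_rates=(1.0, 4.0, 8.0),
                           freqs=(0.3, 0.2, 0.2, 0.3))
        aln = simulate_alignment(tree, np.full(3, 0.08), model, 1000, rng)
        c = pair_counts(aln.row("x"), aln.row("y"))
        pi = c.frequencies
        pr, py = pi[0] + pi[2], pi[1] + pi[3]

        def neg_loglik(params):
            a1, a2, b = np.exp(params)  # rates x time, positive
            # TN93 pair-mismatch probabilities (analytic, via the spectrum)
            e2 = math.exp(-b)
            e3 = math.exp(-(pr * a1 + py * b))
            e4 = math.exp(-(py * a2 + pr * b))
            p1 = 2 * pi[0] * pi[2] / pr * (pr + py * e2 - e3)
            p2 = 2 * pi[1] * pi[3] / py * (py + pr * e2 - e4)
            q = 2 * pr * py * (1 - e2)
            rest = 1 - p1 - p2 - q
            if min(p1, p2, q, rest) <= 0:
                return 1e12
            return -(
                c.n_ag * math.log(p1) + c.n_ct * math.log(p2)
                + c.n_tv * math.log(q)
                + (c.n - c.n_ag - c.n_ct - c.n_tv) * math.log(rest)
            )

        res = optimize.minimize(neg_loglik, np.log([0.1, 0.1, 0.05]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        a1, a2, b = np.exp(res.x)
        d_mle = (
            2 * pi[0] * pi[2] * a1 + 2 * pi[1] * pi[3] * a2
            + 2 * pr * py * b
        )
        assert tn93_gamma_distance(c) == pytest.approx(d_mle, abs=1e-3)

    def test_monotone_in_each_difference_count(self):
        base = dict(n=1000, base_counts=(500, 500, 500, 500))
        grid = range(0, 60, 10)
        for field in ("n_ag", "n_ct", "n_tv"):
            prev = -1.0
            for k in grid:
                counts = dict(n_ag=20, n_ct=20, n_tv=40, **base)
                counts[field] = k
                d = tn93_gamma_distance(PairCounts(**counts))
                assert d > prev
                prev = d

    def test_gamma_correction_increases_distance(self):
        c = PairCounts(40, 40, 80, 1000, (500, 500, 500, 500))
        assert tn93_gamma_distance(c, alpha=0.5) > tn93_gamma_distance(c)

    def test_saturation_flagged(self):
        c = PairCounts(200, 200, 550, 1000, (500, 500, 500, 500))
        with pytest.raises(SaturationError, match="saturation"):
            tn93_gamma_distance(c)


class TestBetweenCladeDistance:
    def test_identical_clades_zero(self):
        aln = Alignment(("a1", "a2", "b1"), ("ACGTAC", "ACGTAC", "ACGTAC"))
        assert between_clade_distance(aln, ["a1", "a2"], ["b1"]) == 0.0

    def test_pooled_close_to_average_on_homogeneous_data(self, rng):
        tree = TimeTree.build(
            ((("a1", "a2", 0.5), "a3", 1.0), (("b1", "b2", 0.5), "b3", 1.0), 5.0)
        )
        model = make_model("HKY", kappa=3.0, freqs=(0.3, 0.2, 0.2, 0.3))
        aln = simulate_alignment(tree, np.full(tree.n_nodes, 0.01), model, 2000, rng)
        a, b = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        pooled = between_clade_distance(aln, a, b, method="pooled")
        avg = between_clade_distance(aln, a, b, method="average")
        assert pooled == pytest.approx(avg, rel=0.05)

    def test_simulation_consistency_at_known_divergence(self):
        """Pooled estimate is within 3 SE of the generating 0.10 subst/site."""
        model = make_model("HKY", kappa=4.0, freqs=(0.3, 0.2, 0.2, 0.3))
        tree = TimeTree.build(("p", "q", 1.0))
        truth = 0.10
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng([901, seed])
            aln = simulate_alignment(tree, np.full(3, truth / 2), model, 1000, rng)
            estimates.append(between_clade_distance(aln, ["p"], ["q"]) / 100)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - truth) < 3 * se


class TestRateArithmetic:
    @pytest.mark.parametrize(
        "dist, age, expected",
        [(1.55, 4.90, 0.32), (5.70, 5.75, 0.99), (0.0, 3.0, 0.0)],
    )
    def test_divergence_rate(self, dist, age, expected):
        assert divergence_rate(dist, age) == expected

    def test_age_must_be_positive(self):
        with pytest.raises(DistanceError):
            divergence_rate(1.0, 0.0)

    def test_round_half_away_from_zero(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.315, 2) == 0.32

    def test_median_of_seven_split_rates(self):
        rates = [0.34, 0.31, 0.34, 0.29, 0.32, 0.32, 0.15]
        assert median_rates(rates) == 0.32

    def test_median_even_count_averages_middle_two(self):
        assert median_rates([0.1, 0.2, 0.3, 0.4]) == 0.25

    def test_median_single_row(self):
        assert median_rates([0.42]) == 0.42


class TestBiasBoundedRates:
    def test_transisthmian_style_bounds(self):
        fastest, slowest = bias_bounded_rates((1.4, 1.7), (3.57, 6.54))
        assert fastest == pytest.approx(1.7 / 3.57, abs=1e-12)
        assert slowest == pytest.approx(1.4 / 6.54, abs=1e-12)

    def test_degenerate_intervals_collapse(self):
        fastest, slowest = bias_bounded_rates((1.5, 1.5), (5.0, 5.0))
        assert fastest == slowest == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_bracket_the_point_rate(self, seed):
        rng = np.random.default_rng(seed)
        d = sorted(rng.uniform(0.5, 5.0, 2))
        a = sorted(rng.uniform(1.0, 10.0, 2))
        fastest, slowest = bias_bounded_rates(tuple(d), tuple(a))
        point = np.mean(d) / np.mean(a)
        assert slowest <= point <= fastest


class TestFoldRatio:
    def test_equal_rates(self):
        assert fold_ratio(0.5, 0.5) == (1.0, "first")

    def test_coi_medians(self):
        ratio, which = fold_ratio(5.12, 0.32)
        assert ratio == pytest.approx(16.0)
        assert which == "first"

    def test_16s_medians_exceed_ten(self):
        ratio, _ = fold_ratio(0.26, 3.58)
        assert ratio == pytest.approx(3.58 / 0.26)
        assert ratio >= 10.0

    def test_zero_rate_rejected(self):
        with pytest.raises(DistanceError):
            fold_ratio(0.0, 1.0)


class TestSpearman:
    def test_perfect_monotone(self):
        r, p = spearman_rate_age([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r == pytest.approx(1.0)

    def test_ties_match_manual_rank_formula(self):
        rates = [0.1, 0.2, 0.2, 0.5, 0.4]
        ages = [5.0, 4.0, 3.0, 2.0, 1.0]
        r, _ = spearman_rate_age(rates, ages)
        rx = stats.rankdata(rates)
        ry = stats.rankdata(ages)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_exact_permutation_p_for_n7(self, rng):
        rates = rng.uniform(0, 1, 7)
        ages = rng.uniform(1, 10, 7)
        r_obs, p = spearman_rate_age(rates, ages)
        rx = stats.rankdata(rates)
        ry = stats.rankdata(ages)

        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]

        count = sum(
            1
            for perm in itertools.permutations(ry)
            if abs(corr(rx, np.array(perm))) >= abs(r_obs) - 1e-12
        )
        assert p == pytest.approx(count / math.factorial(7), abs=1e-12)

    def test_t_approximation_matches_scipy_for_larger_n(self, rng):
        rates = rng.uniform(0, 1, 15)
        ages = rng.uniform(1, 10, 15)
        r, p = spearman_rate_age(rates, ages)
        ref = stats.spearmanr(rates, ages)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_undefined(self):
        with pytest.raises(DistanceError, match="constant"):
            spearman_rate_age([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
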