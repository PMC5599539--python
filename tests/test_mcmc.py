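"""Clock-dating MCMC: priors, moves, traces, HPD and ESS diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleoclock.alignment import concatenate_partitions
from paleoclock.mcmc import (
    CalibrationPrior,
    ClockPrior,
    ConfigurationError,
    McmcSettings,
    Trace,
    build_sampler,
    calibration_mean_from_offset,
    combine_traces,
    effective_sample_size,
    hpd_interval,
    mcmc_run,
    summarize_node_ages,
)
from paleoclock.simulate import draw_branch_rates, simulate_alignment
from paleoclock.submodels import make_model
from paleoclock.timetree import TimeTree

LN20 = math.log(20.0)


@pytest.fixture
def cherry_tree():
    return TimeTree.build((("a", "b", 3.0), ("c", "d", 1.0), 12.0))


@pytest.fixture
def cherry_calibrations():
    return [
        CalibrationPrior(taxa=frozenset("abcd"), offset_ma=11.0, name="root"),
        CalibrationPrior(taxa=frozenset("ab"), offset_ma=2.59, name="ab"),
        CalibrationPrior(taxa=frozenset("cd"), offset_ma=0.78, name="cd"),
    ]


class TestCalibrationRule:
    @pytest.mark.parametrize("offset, expected", [(11.0, 11.0 / LN20), (0.78, 0.78 / LN20)])
    def test_mean_from_offset(self, offset, expected):
        assert calibration_mean_from_offset(offset) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("offset", [0.78, 2.59, 11.0])
    def test_upper_95th_percentile_is_twice_the_fossil_age(self, offset):
        m = calibration_mean_from_offset(offset)
        q95 = stats.expon(loc=offset, scale=m).ppf(0.95)
        assert q95 == pytest.approx(2 * offset, abs=1e-9)

    def test_density_zero_below_offset(self):
        cal = CalibrationPrior(taxa=frozenset("ab"), offset_ma=2.59)
        assert cal.log_density(2.0) == -np.inf
        assert np.isfinite(cal.log_density(2.6))

    def test_invalid_offset_rejected(self):
        with pytest.raises(ConfigurationError):
            calibration_mean_from_offset(0.0)


class TestLogPrior:
    def _sampler(self, tree, cals, clock_prior=None):
        return build_sampler(
            None, None, None, tree, cals, clock_prior or ClockPrior(),
            McmcSettings(chain_length=100, sample_interval=10, root_max_ma=1000.0),
        )

    def test_additivity_against_independent_densities(self, cherry_tree, cherry_calibrations):
        sampler = self._sampler(cherry_tree, cherry_calibrations)
        state = sampler.initial_state(0.01)
        state.ages[cherry_tree.mrca({"a", "b"})] = 4.0
        state.ages[cherry_tree.mrca({"c", "d"})] = 1.5
        state.ages[cherry_tree.root] = 13.0
        state.clock_stdev[:] = 0.4
        state.branch_rates[:, :] = 0.015
        expected = 0.0
        for cal in cherry_calibrations:
            node = cherry_tree.mrca(cal.taxa)
            m = cal.offset_ma / LN20
            expected += stats.expon(loc=cal.offset_ma, scale=m).logpdf(state.ages[node])
        expected += stats.expon(scale=0.333).logpdf(0.4)
        mu = math.log(0.01) - 0.5 * 0.4**2
        n_branches = cherry_tree.n_nodes - 1
        expected += n_branches * stats.lognorm(s=0.4, scale=math.exp(mu)).logpdf(0.015)
        assert sampler.log_prior(state) == pytest.approx(expected, abs=1e-12)

    def test_age_below_offset_is_rejected(self, cherry_tree, cherry_calibrations):
        sampler = self._sampler(cherry_tree, cherry_calibrations)
        state = sampler.initial_state(0.01)
        state.ages[cherry_tree.mrca({"a", "b"})] = 2.0  # below the 2.59 offset
        assert sampler.log_prior(state) == -np.inf

    def test_clock_mean_outside_bounds_is_rejected(self, cherry_tree, cherry_calibrations):
        sampler = self._sampler(cherry_tree, cherry_calibrations)
        state = sampler.initial_state(0.01)
        state.clock_mean[:] = 1e-4  # below the 0.001 lower bound
        assert sampler.log_prior(state) == -np.inf

    def test_ordering_violation_is_rejected(self, cherry_tree, cherry_calibrations):
        sampler = self._sampler(cherry_tree, cherry_calibrations)
        state = sampler.initial_state(0.01)
        state.ages[cherry_tree.root] = 2.9  # younger than the (a,b) node
        assert sampler.log_prior(state) == -np.inf

    def test_non_monophyletic_calibration_rejected(self, cherry_tree):
        with pytest.raises(ConfigurationError, match="monophyletic"):
            self._sampler(
                cherry_tree,
                [CalibrationPrior(taxa=frozenset({"a", "c"}), offset_ma=1.0)],
            )


class TestDetailedBalance:
    def test_acceptance_ratio_matches_independent_evaluation(self, cherry_tree, cherry_calibrations):
        records = []
        sampler = build_sampler(
            None, None, None, cherry_tree, cherry_calibrations, ClockPrior(),
            McmcSettings(chain_length=1000, sample_interval=100, seed=9),
            debug_hook=lambda *a: records.append(a),
        )
        sampler.run()
        assert len(records) == 1000
        checked = 0
        for move, old, new, log_hastings, log_alpha in records:
            lp_old = sampler.log_prior(old)
            lp_new = sampler.log_prior(new)
            if lp_new == -np.inf:
                assert log_alpha == -np.inf
                continue
            expected = lp_new - lp_old + log_hastings
            assert log_alpha == pytest.approx(expected, abs=1e-10), move
            checked += 1
        assert checked > 500


class TestPriorSampling:
    def test_prior_only_run_recovers_calibration_exponentials(
        self, cherry_tree, cherry_calibrations
    ):
        settings = McmcSettings(
            chain_length=60000, sample_interval=20, seed=11, root_max_ma=1000.0
        )
        trace = mcmc_run(
            None, None, None, cherry_tree, cherry_calibrations, ClockPrior(), settings
        )
        assert len(trace) == 60000 // 20 + 1
        for cal in cherry_calibrations:
            node = cherry_tree.mrca(cal.taxa)
            col = trace.age_column(cherry_tree.node_label(node))[300:]
            m = cal.offset_ma / LN20
            ess = effective_sample_size(col)
            se = m / math.sqrt(ess)  # exponential sd equals its mean m
            assert abs(col.mean() - (cal.offset_ma + m)) < 3 * se + 1e-9

    def test_prior_only_run_recovers_ucld_stdev_prior_mean(self, cherry_tree, cherry_calibrations):
        settings = McmcSettings(chain_length=60000, sample_interval=20, seed=12)
        trace = mcmc_run(
            None, None, None, cherry_tree, cherry_calibrations, ClockPrior(), settings
        )
        col = trace.data["ucld.stdev.prior"].to_numpy()[300:]
        ess = effective_sample_size(col)
        se = 0.333 / math.sqrt(ess)
        assert abs(col.mean() - 0.333) < 3 * se


class TestChainBookkeeping:
    def test_sample_count(self, cherry_tree, cherry_calibrations):
        settings = McmcSettings(chain_length=1000, sample_interval=50, seed=1)
        trace = mcmc_run(None, None, None, cherry_tree, cherry_calibrations,
                         ClockPrior(), settings)
        assert len(trace) == 21

    def test_seeded_reproducibility(self, cherry_tree, cherry_calibrations):
        settings = McmcSettings(chain_length=2000, sample_interval=20, seed=42)
        t1 = mcmc_run(None, None, None, cherry_tree, cherry_calibrations,
                      ClockPrior(), settings)
        t2 = mcmc_run(None, None, None, cherry_tree, cherry_calibrations,
                      ClockPrior(), settings)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_starting_ages_inflated_to_satisfy_offsets(self):
        tree = TimeTree.build((("a", "b", 0.5), "c", 1.0))
        cal = [CalibrationPrior(taxa=frozenset("abc"), offset_ma=11.0)]
        settings = McmcSettings(chain_length=100, sample_interval=10)
        with pytest.warns(UserWarning, match="inflated"):
            mcmc_run(None, None, None, tree, cal, ClockPrior(), settings)

    def test_age_ordering_invariant_in_every_sample(self, cherry_tree, cherry_calibrations):
        settings = McmcSettings(chain_length=5000, sample_interval=10, seed=3)
        trace = mcmc_run(None, None, None, cherry_tree, cherry_calibrations,
                         ClockPrior(), settings)
        root = trace.age_column(cherry_tree.node_label(cherry_tree.root))
        for label in ("a+b", "c+d"):
            child = trace.age_column(label)
            assert np.all(root > child)
            assert np.all(child > 0)


class TestCombineTraces:
    def _fake_trace(self, values):
        return Trace(pd.DataFrame({"state": range(len(values)), "x": values}))

    def test_burnin_arithmetic(self):
        t = self._fake_trace(np.arange(1000.0))
        combined = combine_traces([t], burnin=0.10)
        assert len(combined) == 900

    def test_thinning_arithmetic(self):
        traces = [self._fake_trace(np.arange(1000.0)) for _ in range(10)]
        combined = combine_traces(traces, burnin=0.10, thinning=10)
        assert len(combined) == 900

    def test_two_identical_runs_keep_the_median(self):
        t1 = self._fake_trace(np.arange(100.0))
        t2 = self._fake_trace(np.arange(100.0))
        single = combine_traces([t1], burnin=0.0)
        double = combine_traces([t1, t2], burnin=0.0)
        assert np.median(double.data["x"]) == np.median(single.data["x"])

    def test_mismatched_columns_rejected(self):
        t1 = self._fake_trace([1.0])
        t2 = Trace(pd.DataFrame({"state": [0], "y": [1.0]}))
        with pytest.raises(ConfigurationError, match="columns"):
            combine_traces([t1, t2])


class TestHpdInterval:
    def test_constant_samples_zero_width(self):
        lo, hi = hpd_interval(np.full(50, 3.3))
        assert lo == hi == 3.3

    def test_evenly_spaced_points(self):
        lo, hi = hpd_interval(np.arange(100) / 10.0, level=0.95)
        assert (lo, hi) == (0.0, 9.4)

    def test_matches_exhaustive_window_search(self, rng):
        x = np.sort(rng.gamma(2.0, 1.5, size=1000))
        w = math.ceil(0.95 * x.size)
        best = min(
            ((x[i + w - 1] - x[i], x[i], x[i + w - 1]) for i in range(x.size - w + 1)),
            key=lambda t: (t[0], t[1]),
        )
        assert hpd_interval(x) == (best[1], best[2])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([1.0] * 5)


class TestEffectiveSampleSize:
    def test_iid_draws(self, rng):
        x = rng.normal(size=10000)
        assert effective_sample_size(x) == pytest.approx(10000, rel=0.15)

    def test_ar1_closed_form(self, rng):
        rho, n = 0.5, 10000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * math.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.20)

    def test_constant_column_is_undefined_not_a_crash(self):
        assert math.isnan(effective_sample_size(np.full(200, 7.0)))


class TestSummaries:
    def test_median_matches_quantile_oracle_and_order_invariance(
        self, cherry_tree, cherry_calibrations, rng
    ):
        settings = McmcSettings(chain_length=5000, sample_interval=10, seed=8)
        trace = mcmc_run(None, None, None, cherry_tree, cherry_calibrations,
                         ClockPrior(), settings)
        summary = summarize_node_ages(trace, cherry_tree)
        col = trace.age_column("a+b")
        assert summary.loc["a+b", "median_ma"] == pytest.approx(
            np.quantile(col, 0.5), abs=1e-12
        )
        shuffled = Trace(
            trace.data.sample(frac=1.0, random_state=1).reset_index(drop=True),
            node_labels=trace.node_labels,
        )
        summary2 = summarize_node_ages(shuffled, cherry_tree)
        # medians and HPDs are permutation-invariant (ESS is not, by design)
        cols = ["median_ma", "hpd_low", "hpd_high"]
        pd.testing.assert_frame_equal(summary[cols], summary2[cols])


class TestWithData:
    def test_parameter_recovery_rate_contrast_between_partitions(self, rng):
        """Two partitions evolving 10x apart: posterior ucld.mean ratio
        within a factor of two of the truth at 1000 sites."""
        tree = TimeTree.build(((("a", "b", 2.0), ("c", "d", 4.0), 8.0),
                               ("e", "f", 5.0), 12.0))
        model = make_model("HKY", kappa=4.0, freqs=(0.3, 0.2, 0.2, 0.3))
        slow, fast = 0.002, 0.02
        named = []
        for gene, mean in (("slow", slow), ("fast", fast)):
            rates = draw_branch_rates(tree, mean, 0.1, rng)
            named.append((gene, simulate_alignment(tree, rates, model, 1000, rng)))
        concat, scheme = concatenate_partitions(named)
        cals = [
            CalibrationPrior(frozenset("abcdef"), 0.8 * 12, name="root"),
            CalibrationPrior(frozenset("abcd"), 0.8 * 8, name="inner"),
        ]
        settings = McmcSettings(chain_length=60000, sample_interval=60, seed=5,
                                thinning=1, root_max_ma=100.0)
        trace = mcmc_run(concat, scheme, {"slow": model, "fast": model}, tree,
                         cals, ClockPrior(), settings)
        burn = trace.data.iloc[int(0.2 * len(trace)):]
        ratio = np.median(burn["ucld.mean.fast"] / burn["ucld.mean.slow"])
        assert 5.0 < ratio < 20.0
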