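"""MCMC node-age inference under an uncorrelated lognormal relaxed clock.

The topology is fixed; the sampler moves node ages (uniform-window redraws
bounded by parent and children, plus root-age scaling), per-partition clock
parameters (ucld.mean, ucld.stdev), and per-partition per-branch rates.
Branch rates are continuous i.i.d. lognormal draws: ucld.mean is the
real-space mean and ucld.stdev the log-space standard deviation.

Priors follow the fossil-calibration setup: each calibrated clade's MRCA age
gets an exponential prior offset at the fossil's minimum age, with the
exponential mean chosen so the prior's 95th percentile is twice the fossil
age; ucld.mean is uniform on a wide interval, ucld.stdev exponential; node
ages are otherwise uniform subject to parent-older-than-child ordering and a
root-age cap.

Trace handling mirrors the usual relaxed-clock workflow: multiple seeded
runs, per-run burn-in removal, concatenation and thinning, then per-node
medians, 95% HPD intervals and effective sample sizes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, PartitionScheme
from .likelihood import PartitionLikelihood
from .submodels import ModelSpec
from .timetree import TimeTree

LOG_20 = math.log(20.0)


class ConfigurationError(ValueError):
    """Raised for inconsistent prior/tree/partition configuration."""


class TuningFailureWarning(UserWarning):
    """Emitted when a diagnostic window of proposals accepts nothing."""


def calibration_mean_from_offset(offset_ma: float) -> float:
    """Exponential-prior mean from a fossil minimum age.

    Solves ``offset + mean * ln(20) = 2 * offset`` so the prior's upper 95th
    percentile sits at twice the fossil age: ``mean = offset / ln(20)``.
    """
    if offset_ma <= 0:
        raise ConfigurationError(f"fossil offset must be positive, got {offset_ma}")
    return offset_ma / LOG_20


@dataclass(frozen=True)
class CalibrationPrior:
    """Fossil calibration: exponential node-age prior offset at the fossil age.

    ``taxa`` define the calibrated clade (the MRCA of these tips, which must
    be exactly the clade's tip set in the fixed topology).  ``mean_my``
    defaults to ``offset_ma / ln(20)``.
    """

    taxa: frozenset
    offset_ma: float
    mean_my: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.offset_ma <= 0:
            raise ConfigurationError("calibration offset must be positive")
        if self.mean_my is not None and self.mean_my <= 0:
            raise ConfigurationError("calibration mean must be positive")
        if len(self.taxa) < 1:
            raise ConfigurationError("calibration clade needs at least one tip")

    @property
    def mean(self) -> float:
        return self.mean_my if self.mean_my is not None else calibration_mean_from_offset(self.offset_ma)

    def log_density(self, age: float) -> float:
        """Log prior density of the MRCA age (zero mass below the offset)."""
        if age < self.offset_ma:
            return -np.inf
        m = self.mean
        return -math.log(m) - (age - self.offset_ma) / m


@dataclass(frozen=True)
class ClockPrior:
    """Priors on the per-partition clock parameters."""

    mean_lower: float = 0.001
    mean_upper: float = 1e100
    stdev_prior_mean: float = 0.333

    def __post_init__(self):
        if not self.mean_lower < self.mean_upper:
            raise ConfigurationError("ucld.mean bounds must satisfy lower < upper")
        if self.stdev_prior_mean <= 0:
            raise ConfigurationError("ucld.stdev prior mean must be positive")


@dataclass(frozen=True)
class McmcSettings:
    """Chain bookkeeping and proposal step sizes."""

    chain_length: int = 100_000
    sample_interval: int = 100
    n_runs: int = 1
    burnin: float = 0.10
    thinning: int = 10
    seed: int = 1
    root_max_ma: float = 1000.0
    root_scale_step: float = 0.4
    mean_scale_step: float = 0.8
    stdev_scale_step: float = 0.8
    rate_scale_step: float = 0.8
    ratetime_scale_step: float = 0.15
    diagnostic_window: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.burnin < 1.0:
            raise ConfigurationError("burn-in fraction must be in [0, 1)")
        if self.chain_length % self.sample_interval:
            raise ConfigurationError(
                "chain length must be divisible by the sampling interval"
            )
        if self.thinning < 1 or self.n_runs < 1:
            raise ConfigurationError("thinning and run count must be >= 1")


@dataclass
class ClockState:
    """One MCMC state: node ages plus per-partition clock parameters."""

    ages: np.ndarray                 # (n_nodes,), tips fixed at 0
    clock_mean: np.ndarray           # (n_partitions,)
    clock_stdev: np.ndarray          # (n_partitions,)
    branch_rates: np.ndarray         # (n_partitions, n_nodes); root col unused

    def copy(self) -> "ClockState":
        return ClockState(
            self.ages.copy(),
            self.clock_mean.copy(),
            self.clock_stdev.copy(),
            self.branch_rates.copy(),
        )


@dataclass
class Trace:
    """Posterior samples with provenance.

    ``data`` columns: state, posterior, likelihood, prior, the per-partition
    ucld parameters, and one ``age(<node label>)`` column per internal node.
    """

    data: pd.DataFrame
    node_labels: dict = field(default_factory=dict)
    run_id: int = 0
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.data)

    def age_column(self, label: str) -> np.ndarray:
        return self.data[f"age({label})"].to_numpy()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# run={self.run_id} seed={self.seed}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Trace":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


class ClockDatingSampler:
    """Metropolis-Hastings sampler for node ages on a fixed topology.

    Parameters
    ----------
    tree:
        Starting tree (its topology is never altered); ages violating a
        calibration offset are inflated with a warning.
    partitions:
        ``(gene name, PartitionLikelihood or None)`` pairs; ``None`` anywhere
        disables the likelihood (prior-only sampling).
    calibrations, clock_prior:
        Prior configuration.  Every calibration clade must be monophyletic in
        the tree, checked at startup.
    """

    def __init__(
        self,
        tree: TimeTree,
        partitions,
        calibrations,
        clock_prior: ClockPrior,
        settings: McmcSettings,
        debug_hook=None,
        auto_initial_means=None,
    ):
        self.auto_initial_means = auto_initial_means
        self.tree = tree.copy()
        self.names = [name for name, _ in partitions]
        self.likelihoods = [pl for _, pl in partitions]
        self.use_likelihood = all(pl is not None for pl in self.likelihoods)
        self.calibrations = list(calibrations)
        self.clock_prior = clock_prior
        self.settings = settings
        self.debug_hook = debug_hook
        self.n_part = len(self.names)
        tree_sets = self.tree.tip_sets()
        self.cal_nodes = []
        for cal in self.calibrations:
            node = self.tree.mrca(cal.taxa)
            if tree_sets[node] != frozenset(cal.taxa):
                raise ConfigurationError(
                    f"calibration clade {sorted(cal.taxa)} is not monophyletic "
                    "in the fixed topology"
                )
            self.cal_nodes.append(node)
        self._nonroot = np.flatnonzero(np.arange(tree.n_nodes) != tree.root)
        self._internal_nonroot = np.array(
            [i for i in tree.internal_nodes if i != tree.root], dtype=np.int64
        )
        # per-internal-node subtree index lists for subtree moves
        self._subtree_branches = {}   # branches (child-node ids) under v, v incl. unless root
        self._subtree_internal = {}   # internal nodes in the subtree, v included
        self._subtree_inner = {}      # subtree nodes except v: branches fully inside
        for v in self.tree.internal_nodes:
            v = int(v)
            nodes = []
            stack = [v]
            while stack:
                node = stack.pop()
                nodes.append(node)
                for ch in (self.tree.left[node], self.tree.right[node]):
                    if ch >= 0:
                        stack.append(int(ch))
            self._subtree_branches[v] = np.asarray(
                sorted(n for n in nodes if n != self.tree.root), dtype=np.int64
            )
            self._subtree_internal[v] = np.asarray(
                sorted(n for n in nodes if n >= self.tree.n_tips), dtype=np.int64
            )
            self._subtree_inner[v] = np.asarray(
                sorted(n for n in nodes if n != v), dtype=np.int64
            )

    # -- prior ------------------------------------------------------------

    def log_prior(self, state: ClockState) -> float:
        """Joint log prior: tree process, calibrations, clock, branch rates."""
        tree, ages = self.tree, state.ages
        if ages[tree.root] > self.settings.root_max_ma:
            return -np.inf
        parents = tree.parent[self._nonroot]
        if np.any(ages[parents] <= ages[self._nonroot]):
            return -np.inf
        lp = 0.0
        for cal, node in zip(self.calibrations, self.cal_nodes):
            lp += cal.log_density(float(ages[node]))
            if lp == -np.inf:
                return -np.inf
        cp = self.clock_prior
        if np.any(state.clock_mean < cp.mean_lower) or np.any(
            state.clock_mean > cp.mean_upper
        ):
            return -np.inf
        if np.any(state.clock_stdev <= 0):
            return -np.inf
        lp += float(
            np.sum(
                -state.clock_stdev / cp.stdev_prior_mean
                - math.log(cp.stdev_prior_mean)
            )
        )
        # i.i.d. lognormal branch rates: real-space mean m, log-space sd s
        rates = state.branch_rates[:, self._nonroot]
        if np.any(rates <= 0):
            return -np.inf
        s = state.clock_stdev[:, None]
        mu = np.log(state.clock_mean)[:, None] - 0.5 * s**2
        z = (np.log(rates) - mu) / s
        lp += float(
            np.sum(-0.5 * z**2 - np.log(rates * s) - 0.5 * math.log(2 * math.pi))
        )
        return lp

    # -- likelihood -------------------------------------------------------

    def partition_log_likelihood(self, state: ClockState, p: int) -> float:
        if not self.use_likelihood:
            return 0.0
        durations = self.tree.durations(state.ages)
        lengths = durations * state.branch_rates[p]
        return self.likelihoods[p].log_likelihood(lengths)

    def log_likelihood(self, state: ClockState) -> float:
        return sum(self.partition_log_likelihood(state, p) for p in range(self.n_part))

    # -- initial state ----------------------------------------------------

    def initial_state(self, initial_clock_mean: float | None = None) -> ClockState:
        if initial_clock_mean is None:
            if self.auto_initial_means is not None:
                init_means = np.asarray(self.auto_initial_means, dtype=float)
            else:
                init_means = np.full(self.n_part, 0.01)
        else:
            init_means = np.full(self.n_part, float(initial_clock_mean))
        init_means = np.clip(
            init_means, self.clock_prior.mean_lower, self.clock_prior.mean_upper
        )
        ages = self.tree.ages.copy()
        factor = 1.0
        for cal, node in zip(self.calibrations, self.cal_nodes):
            if ages[node] < cal.offset_ma:
                factor = max(factor, cal.offset_ma / ages[node] * 1.05)
        if factor > 1.0:
            warnings.warn(
                f"starting ages inflated by {factor:.3g} to satisfy "
                "calibration offsets",
                stacklevel=2,
            )
            internal = self.tree.internal_nodes
            ages[internal] = ages[internal] * factor
        mean = init_means.copy()
        stdev = np.full(self.n_part, 0.1)
        rates = np.tile(init_means[:, None], (1, self.tree.n_nodes))
        return ClockState(ages, mean, stdev, rates)

    # -- proposals --------------------------------------------------------

    def _propose(self, state: ClockState, rng) -> tuple[str, float, list[int]]:
        """Mutate ``state`` in place; return (move, log-Hastings, partitions
        whose likelihood changed)."""
        tree, st = self.tree, self.settings
        all_parts = list(range(self.n_part))
        u = rng.random()
        has_internal = self._internal_nonroot.size > 0

        def scale(step):
            c = math.exp(step * (rng.random() - 0.5))
            return c, math.log(c)

        if u < 0.30 and has_internal:
            node = int(self._internal_nonroot[rng.integers(self._internal_nonroot.size)])
            lo = max(state.ages[tree.left[node]], state.ages[tree.right[node]])
            hi = state.ages[tree.parent[node]]
            if u < 0.15:
                # full uniform redraw within the fixed parent/child window
                state.ages[node] = lo + (hi - lo) * rng.random()
                return "node_age", 0.0, all_parts
            # small reflected step within the window (symmetric)
            x = state.ages[node] + 0.25 * (hi - lo) * (rng.random() - 0.5)
            while x < lo or x > hi:
                if x < lo:
                    x = 2 * lo - x
                if x > hi:
                    x = 2 * hi - x
            state.ages[node] = x
            return "node_age_window", 0.0, all_parts
        if u < 0.40:
            c, logc = scale(st.root_scale_step)
            state.ages[tree.root] *= c
            return "root_scale", logc, all_parts
        if u < 0.46:
            # rate-time rescaling: ages * c, all branch rates / c; branch
            # lengths (duration x rate) are invariant, so no likelihood change
            c, logc = scale(st.ratetime_scale_step)
            internal = tree.internal_nodes
            state.ages[internal] *= c
            state.branch_rates /= c
            k = internal.size - state.branch_rates.shape[0] * self._nonroot.size
            return "rate_time", k * logc, []
        if u < 0.56:
            # local rate-time rescaling of one subtree: ages in the subtree
            # scale by c, rates of branches fully inside scale by 1/c, so only
            # the subtree's stem branch length changes.  Lets one clade trade
            # rate against time without disturbing the rest of the tree.
            internal = tree.internal_nodes
            v = int(internal[rng.integers(internal.size)])
            c, logc = scale(st.ratetime_scale_step)
            sub_internal = self._subtree_internal[v]
            inner = self._subtree_inner[v]
            state.ages[sub_internal] *= c
            if inner.size:
                state.branch_rates[:, inner] /= c
            k = sub_internal.size - state.branch_rates.shape[0] * inner.size
            parts = [] if v == tree.root else all_parts
            return "subtree_rate_time", k * logc, parts
        if u < 0.62:
            p = int(rng.integers(self.n_part))
            c, logc = scale(st.mean_scale_step)
            state.clock_mean[p] *= c
            state.branch_rates[p] *= c
            return "mean_rates_scale", (1 + self._nonroot.size) * logc, [p]
        if u < 0.66:
            p = int(rng.integers(self.n_part))
            c, logc = scale(st.mean_scale_step)
            state.clock_mean[p] *= c
            return "mean_scale", logc, []
        if u < 0.72:
            p = int(rng.integers(self.n_part))
            c, logc = scale(st.stdev_scale_step)
            state.clock_stdev[p] *= c
            return "stdev_scale", logc, []
        if u < 0.80:
            # scale every branch rate in one subtree of one partition:
            # mixes clade-specific rate contrasts that single-branch moves
            # only reach slowly
            p = int(rng.integers(self.n_part))
            internal = self.tree.internal_nodes
            v = int(internal[rng.integers(internal.size)])
            branches = self._subtree_branches[v]
            c, logc = scale(st.rate_scale_step)
            state.branch_rates[p, branches] *= c
            return "subtree_rates_scale", branches.size * logc, [p]
        p = int(rng.integers(self.n_part))
        node = int(self._nonroot[rng.integers(self._nonroot.size)])
        c, logc = scale(st.rate_scale_step)
        state.branch_rates[p, node] *= c
        return "branch_rate_scale", logc, [p]

    # -- main loop --------------------------------------------------------

    def run(
        self,
        run_id: int = 0,
        initial_clock_mean: float | None = None,
    ) -> Trace:
        """One Metropolis-Hastings chain; reproducible given settings.seed."""
        st = self.settings
        rng = np.random.default_rng([st.seed, run_id])
        state = self.initial_state(initial_clock_mean)
        lp = self.log_prior(state)
        if lp == -np.inf:
            raise ConfigurationError("starting state has zero prior probability")
        part_ll = np.array(
            [self.partition_log_likelihood(state, p) for p in range(self.n_part)]
        )
        tree = self.tree
        internal = tree.internal_nodes
        labels = {int(i): tree.node_label(int(i)) for i in internal}
        n_samples = st.chain_length // st.sample_interval + 1
        n_cols = 4 + 2 * self.n_part + internal.size
        samples = np.empty((n_samples, n_cols))
        row = 0

        def record(step):
            nonlocal row
            ll = part_ll.sum()
            vals = [step, lp + ll, ll, lp]
            vals.extend(state.clock_mean)
            vals.extend(state.clock_stdev)
            vals.extend(state.ages[internal])
            samples[row] = vals
            row += 1

        record(0)
        accepted_in_window = 0
        proposals_in_window = 0
        warned = False
        for step in range(1, st.chain_length + 1):
            proposal = state.copy()
            move, log_hastings, parts = self._propose(proposal, rng)
            lp_new = self.log_prior(proposal)
            if lp_new == -np.inf:
                log_alpha = -np.inf
                new_ll = None
            else:
                new_ll = part_ll.copy()
                for p in parts:
                    new_ll[p] = self.partition_log_likelihood(proposal, p)
                log_alpha = (
                    (lp_new + new_ll.sum()) - (lp + part_ll.sum()) + log_hastings
                )
            if self.debug_hook is not None:
                self.debug_hook(move, state.copy(), proposal.copy(), log_hastings, log_alpha)
            if log_alpha >= 0 or math.log(rng.random()) < log_alpha:
                state = proposal
                lp = lp_new
                if new_ll is not None:
                    part_ll = new_ll
                accepted_in_window += 1
            proposals_in_window += 1
            if proposals_in_window >= st.diagnostic_window:
                if accepted_in_window == 0 and not warned:
                    warnings.warn(
                        f"no proposals accepted in a window of "
                        f"{st.diagnostic_window} steps: proposal tuning failure",
                        TuningFailureWarning,
                        stacklevel=2,
                    )
                    warned = True
                accepted_in_window = 0
                proposals_in_window = 0
            if step % st.sample_interval == 0:
                record(step)
        cols = ["state", "posterior", "likelihood", "prior"]
        cols += [f"ucld.mean.{g}" for g in self.names]
        cols += [f"ucld.stdev.{g}" for g in self.names]
        cols += [f"age({labels[int(i)]})" for i in internal]
        frame = pd.DataFrame(samples, columns=cols)
        frame["state"] = frame["state"].astype(int)
        return Trace(frame, node_labels=labels, run_id=run_id, seed=st.seed)


def build_sampler(
    alignment: Alignment | None,
    scheme: PartitionScheme | None,
    models: dict[str, ModelSpec] | None,
    tree: TimeTree,
    calibrations,
    clock_prior: ClockPrior,
    settings: McmcSettings,
    debug_hook=None,
) -> ClockDatingSampler:
    """Wire partition likelihoods to a sampler.

    With ``alignment=None`` the sampler targets the prior only (one dummy
    partition named ``prior`` so clock parameters are still sampled).
    """
    if alignment is None:
        partitions = [("prior", None)]
        auto_means = None
    else:
        if scheme is None or models is None:
            raise ConfigurationError("need a partition scheme and models")
        partitions = []
        auto_means = []
        for gene in scheme.genes:
            if gene not in models:
                raise ConfigurationError(f"no model for partition {gene!r}")
            part_aln = scheme.extract(alignment, gene)
            partitions.append(
                (gene, PartitionLikelihood(part_aln, tree, models[gene]))
            )
            auto_means.append(crude_clock_mean(part_aln, tree))
    return ClockDatingSampler(
        tree, partitions, calibrations, clock_prior, settings, debug_hook,
        auto_initial_means=auto_means,
    )


def crude_clock_mean(alignment: Alignment, tree: TimeTree) -> float:
    """Rough per-partition starting rate (substitutions/site/My).

    Averages the Jukes-Cantor-corrected p-distance over a few tip pairs
    spanning the root and divides by twice the root age.  Only used to start
    chains near the right order of magnitude; the posterior is unaffected.
    """
    sets = tree.tip_sets()
    left = sorted(sets[int(tree.left[tree.root])])
    right = sorted(sets[int(tree.right[tree.root])])
    dists = []
    for a, b in itertools.islice(itertools.product(left, right), 8):
        sa, sb = alignment.row(a), alignment.row(b)
        same = diff = 0
        for x, y in zip(sa, sb):
            if x in "ACGT" and y in "ACGT":
                if x == y:
                    same += 1
                else:
                    diff += 1
        if same + diff == 0:
            continue
        p = diff / (same + diff)
        if p < 0.70:
            dists.append(-0.75 * math.log1p(-4.0 * p / 3.0))
        else:
            dists.append(1.5)
    if not dists:
        return 0.01
    d = float(np.mean(dists))
    root_age = float(tree.ages[tree.root])
    return max(d / (2.0 * root_age), 1e-4)


def mcmc_run(
    alignment: Alignment | None,
    scheme: PartitionScheme | None,
    models: dict[str, ModelSpec] | None,
    tree: TimeTree,
    calibrations,
    clock_prior: ClockPrior,
    settings: McmcSettings,
    run_id: int = 0,
    initial_clock_mean: float | None = None,
) -> Trace:
    """One seeded MCMC run (see :class:`ClockDatingSampler`)."""
    sampler = build_sampler(
        alignment, scheme, models, tree, calibrations, clock_prior, settings
    )
    return sampler.run(run_id=run_id, initial_clock_mean=initial_clock_mean)


def run_chains(sampler: ClockDatingSampler, initial_clock_mean: float | None = None) -> list[Trace]:
    """All configured independent runs (run ids 0..n_runs-1)."""
    return [
        sampler.run(run_id=i, initial_clock_mean=initial_clock_mean)
        for i in range(sampler.settings.n_runs)
    ]


def combine_traces(traces, burnin: float = 0.10, thinning: int = 1) -> Trace:
    """Remove per-run burn-in, concatenate, and regularly thin."""
    if not traces:
        raise ConfigurationError("no traces to combine")
    cols = list(traces[0].data.columns)
    for t in traces[1:]:
        if list(t.data.columns) != cols:
            raise ConfigurationError("traces have mismatched columns")
    if not 0.0 <= burnin < 1.0:
        raise ConfigurationError("burn-in fraction must be in [0, 1)")
    kept = []
    for t in traces:
        n = len(t.data)
        kept.append(t.data.iloc[int(burnin * n):])
    combined = pd.concat(kept, ignore_index=True)
    if thinning > 1:
        combined = combined.iloc[::thinning].reset_index(drop=True)
    return Trace(
        combined, node_labels=dict(traces[0].node_labels), run_id=-1,
        seed=traces[0].seed,
    )


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(level * n)`` samples.

    Ties in width are broken by the earliest (lowest) window.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    w = math.ceil(level * n)
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1:] - x[: n - w + 1]
    # earliest window among effective ties (tolerance absorbs fp noise)
    wmin = float(widths.min())
    tol = 1e-12 * max(abs(wmin), abs(float(x[-1] - x[0])), 1.0)
    i = int(np.flatnonzero(widths <= wmin + tol)[0])
    return float(x[i]), float(x[i + w - 1])


def effective_sample_size(samples) -> float:
    """ESS via Geyer's initial-positive-sequence autocorrelation sum.

    Returns ``nan`` (undefined) for a constant column rather than raising.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for an ESS estimate")
    if np.ptp(x) == 0:
        return float("nan")
    x = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = -1.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if gamma <= 0.0:
            break
        tau += 2.0 * gamma
        m += 1
    tau = max(tau, 1e-8)
    return float(n / tau)


def summarize_node_ages(trace: Trace, tree: TimeTree) -> pd.DataFrame:
    """Per-internal-node posterior summary: median, 95% HPD, ESS.

    Rows are labeled by the tree's node labels (stable MRCA-derived names);
    summaries are invariant to sample order.
    """
    rows = []
    for node in tree.internal_nodes:
        label = tree.node_label(int(node))
        col = f"age({label})"
        if col not in trace.data.columns:
            raise ConfigurationError(f"trace lacks column {col!r}")
        x = trace.data[col].to_numpy()
        lo, hi = hpd_interval(x)
        try:
            ess = effective_sample_size(x)
        except ValueError:
            ess = float("nan")
        rows.append(
            {
                "node": label,
                "median_ma": float(np.median(x)),
                "hpd_low": lo,
                "hpd_high": hi,
                "ess": ess,
            }
        )
    return pd.DataFrame(rows).set_index("node")
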