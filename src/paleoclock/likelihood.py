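"""Partitioned phylogenetic likelihood by the pruning algorithm.

Site patterns are compressed, ambiguity codes become partial-likelihood
vectors with 1 for every compatible state ('N' and '-' are full uncertainty),
and per-node rescaling with log accumulators keeps partial likelihoods in
range even under extreme gamma shapes (the smallest category rate at
alpha ~ 0.02 is astronomically small).  The site likelihood mixes rate
classes (invariant + discrete gamma) at the root.

The inner loop is JIT-compiled with numba; a brute-force enumeration over
ancestral state assignments is provided as an independent oracle for small
trees.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numba import njit

from .alignment import Alignment
from .submodels import (
    ModelSpec,
    RateMatrix,
    build_rate_matrix,
    site_rate_mixture,
    transition_probabilities,
    transition_probability_tensor,
)
from .timetree import TimeTree, TreeError

#: IUPAC nucleotide codes as bitmasks over (A, C, G, T).
IUPAC_MASKS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b1111,
}


class LikelihoodError(ValueError):
    """Raised for inputs the likelihood machinery cannot handle."""


def encode_states(alignment: Alignment, taxa_order) -> np.ndarray:
    """Bitmask matrix (n_taxa, n_sites) in the given taxon order."""
    rows = []
    for taxon in taxa_order:
        seq = alignment.row(taxon)
        try:
            rows.append([IUPAC_MASKS[c] for c in seq])
        except KeyError as exc:
            raise LikelihoodError(f"invalid state character {exc} in {taxon!r}")
    return np.asarray(rows, dtype=np.uint8)


def compress_patterns(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (columns) and their multiplicities."""
    patterns, counts = np.unique(states, axis=1, return_counts=True)
    return patterns, counts.astype(np.float64)


def _tip_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_taxa, 4, n_patterns) partial-likelihood vectors from bitmasks."""
    n_taxa, npat = patterns.shape
    out = np.zeros((n_taxa, 4, npat))
    for s in range(4):
        out[:, s, :] = (patterns >> s) & 1
    return out


@njit(cache=True)
def _prune_kernel(post, left, right, n_tips, tip_part, pmats, pi, weights, counts):
    n_nodes = pmats.shape[0]
    ncat = pmats.shape[1]
    npat = tip_part.shape[2]
    partial = np.zeros((n_nodes, ncat, 4, npat))
    logscale = np.zeros((ncat, npat))
    for tip in range(n_tips):
        for c in range(ncat):
            for s in range(4):
                for p in range(npat):
                    partial[tip, c, s, p] = tip_part[tip, s, p]
    for k in range(post.shape[0]):
        node = post[k]
        l = left[node]
        r = right[node]
        for c in range(ncat):
            pl = pmats[l, c]
            pr = pmats[r, c]
            for p in range(npat):
                m = 0.0
                for s in range(4):
                    accl = 0.0
                    accr = 0.0
                    for t in range(4):
                        accl += pl[s, t] * partial[l, c, t, p]
                        accr += pr[s, t] * partial[r, c, t, p]
                    v = accl * accr
                    partial[node, c, s, p] = v
                    if v > m:
                        m = v
                if m > 0.0:
                    if m < 1e-80:
                        for s in range(4):
                            partial[node, c, s, p] /= m
                        logscale[c, p] += math.log(m)
                else:
                    logscale[c, p] = -np.inf
    root = post[post.shape[0] - 1]
    lnl = 0.0
    for p in range(npat):
        best = -np.inf
        lc = np.empty(ncat)
        for c in range(ncat):
            dot = 0.0
            for s in range(4):
                dot += pi[s] * partial[root, c, s, p]
            if dot > 0.0 and weights[c] > 0.0 and np.isfinite(logscale[c, p]):
                lc[c] = math.log(weights[c] * dot) + logscale[c, p]
            else:
                lc[c] = -np.inf
            if lc[c] > best:
                best = lc[c]
        if best == -np.inf:
            return -np.inf
        acc = 0.0
        for c in range(ncat):
            if lc[c] > -np.inf:
                acc += math.exp(lc[c] - best)
        lnl += counts[p] * (best + math.log(acc))
    return lnl


class PartitionLikelihood:
    """Pruning likelihood for one alignment partition on a fixed topology.

    Binds the compressed site patterns, the model's rate matrix and its
    site-rate mixture to a tree; each call to :meth:`log_likelihood` takes
    per-branch expected-substitution lengths, so MCMC over node ages and
    branch rates re-uses all precomputation.
    """

    def __init__(self, alignment: Alignment, tree: TimeTree, model: ModelSpec):
        missing = set(tree.labels) - set(alignment.taxa)
        if missing:
            raise LikelihoodError(f"taxa missing from alignment: {sorted(missing)}")
        self.tree = tree
        self.model = model
        states = encode_states(alignment, tree.labels)
        self.patterns, self.counts = compress_patterns(states)
        self.n_sites = int(self.counts.sum())
        self.tip_part = _tip_partials(self.patterns)
        self.rate_matrix: RateMatrix = build_rate_matrix(model)
        mixture = site_rate_mixture(model)
        self.cat_rates = np.array([r for r, _ in mixture])
        self.cat_weights = np.array([w for _, w in mixture])

    def log_likelihood(self, branch_lengths: np.ndarray) -> float:
        """Log-likelihood given expected substitutions/site per branch.

        ``branch_lengths`` is indexed by child node; the root entry is
        ignored.  Returns ``-inf`` for data impossible under the model (e.g.
        conflicting tips joined by zero-length paths).
        """
        bl = np.asarray(branch_lengths, dtype=float)
        if bl.shape != (self.tree.n_nodes,):
            raise LikelihoodError(
                f"expected {self.tree.n_nodes} branch lengths, got {bl.shape}"
            )
        lengths = bl[:, None] * self.cat_rates[None, :]
        lengths[self.tree.root, :] = 0.0
        pmats = transition_probability_tensor(self.rate_matrix, lengths)
        return float(
            _prune_kernel(
                self.tree.postorder,
                self.tree.left,
                self.tree.right,
                self.tree.n_tips,
                self.tip_part,
                pmats,
                self.rate_matrix.pi,
                self.cat_weights,
                self.counts,
            )
        )


def _branch_lengths(tree: TimeTree, branch_rates, ages=None) -> np.ndarray:
    rates = np.asarray(branch_rates, dtype=float)
    if rates.ndim == 0:
        rates = np.full(tree.n_nodes, float(rates))
    durations = tree.durations(ages)
    nonroot = np.arange(tree.n_nodes) != tree.root
    if np.any(rates[nonroot] <= 0):
        raise TreeError("branch rates must be strictly positive")
    return durations * rates


def pruning_log_likelihood(
    alignment: Alignment,
    tree: TimeTree,
    branch_rates,
    model: ModelSpec,
) -> float:
    """Pruning log-likelihood of one partition.

    ``branch_rates`` is a scalar or a per-node array of rates in
    substitutions/site/My (indexed by child node; root ignored).
    """
    pl = PartitionLikelihood(alignment, tree, model)
    return pl.log_likelihood(_branch_lengths(tree, branch_rates))


def brute_force_log_likelihood(
    alignment: Alignment,
    tree: TimeTree,
    branch_rates,
    model: ModelSpec,
    max_tips: int = 6,
) -> float:
    """Exhaustive-likelihood oracle for small trees.

    Sums over every assignment of states to internal nodes and every
    site-rate class; exponential in tip count, guarded at ``max_tips``.
    """
    if tree.n_tips > max_tips:
        raise LikelihoodError(f"brute force limited to {max_tips} tips")
    bl = _branch_lengths(tree, branch_rates)
    rm = build_rate_matrix(model)
    mixture = site_rate_mixture(model)
    states = encode_states(alignment, tree.labels)
    internal = list(tree.postorder)
    pi = rm.pi
    n_sites = states.shape[1]
    lnl = 0.0
    pmats = {
        (node, ci): transition_probabilities(rm, bl[node] * rate)
        for node in range(tree.n_nodes)
        if node != tree.root
        for ci, (rate, _) in enumerate(mixture)
    }
    for site in range(n_sites):
        site_lik = 0.0
        for ci, (rate, weight) in enumerate(mixture):
            cat_lik = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                state_of = dict(zip(internal, assign))
                term = pi[state_of[tree.root]]
                for node in range(tree.n_nodes):
                    if node == tree.root:
                        continue
                    parent_state = state_of[int(tree.parent[node])]
                    if node < tree.n_tips:
                        mask = int(states[node, site])
                        p = sum(
                            pmats[(node, ci)][parent_state, s]
                            for s in range(4)
                            if (mask >> s) & 1
                        )
                    else:
                        p = pmats[(node, ci)][parent_state, state_of[node]]
                    term *= p
                    if term == 0.0:
                        break
                cat_lik += term
            site_lik += weight * cat_lik
        if site_lik <= 0.0:
            return -np.inf
        lnl += math.log(site_lik)
    return lnl
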