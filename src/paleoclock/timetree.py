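"""Rooted, dated, strictly bifurcating trees.

Node ages are in Ma with extant tips at age 0; a branch's duration is the
parent age minus the child age, and its expected number of substitutions is
duration times the branch's rate (substitutions/site/My).

The tree is stored in flat arrays (parent/child indices, ages) so node-age
MCMC moves and likelihood evaluation are cheap.  Tips occupy indices
``0..n_tips-1`` in label-input order; internal nodes follow.  Newick I/O goes
through dendropy, with branch lengths carrying durations in My.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for invalid tree structure or dating."""


class TimeTree:
    """A rooted binary tree with node ages (Ma, tips at 0)."""

    def __init__(self, labels, parent, left, right, ages):
        self.labels = tuple(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=float).copy()
        n = self.parent.size
        self.n_tips = len(self.labels)
        self.n_nodes = n
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"expected exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self._tip_index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._tip_index) != self.n_tips:
            raise TreeError("duplicate tip labels")
        self.postorder = self._compute_postorder()
        self._tip_sets: list[frozenset] | None = None
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def build(cls, structure) -> "TimeTree":
        """Build from nested tuples: a tip is a label string, an internal
        node is ``(left, right, age)``."""
        tips: list[str] = []

        def collect(node):
            if isinstance(node, str):
                tips.append(node)
            else:
                collect(node[0])
                collect(node[1])

        collect(structure)
        n_tips = len(tips)
        n_nodes = 2 * n_tips - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        left = np.full(n_nodes, -1, dtype=np.int64)
        right = np.full(n_nodes, -1, dtype=np.int64)
        ages = np.zeros(n_nodes)
        tip_ids = iter(range(n_tips))
        internal_ids = iter(range(n_tips, n_nodes))

        def assign(node) -> int:
            if isinstance(node, str):
                return next(tip_ids)
            if len(node) != 3:
                raise TreeError("internal node must be (left, right, age)")
            l_id = assign(node[0])
            r_id = assign(node[1])
            me = next(internal_ids)
            parent[l_id] = parent[r_id] = me
            left[me], right[me] = l_id, r_id
            ages[me] = float(node[2])
            return me

        assign(structure)
        return cls(tips, parent, left, right, ages)

    @classmethod
    def from_newick(cls, source: str, age_tolerance: float = 1e-6) -> "TimeTree":
        """Parse a dated Newick tree whose branch lengths are durations (My).

        The tree must be rooted, binary, and ultrametric: all tips at the
        same depth (within ``age_tolerance`` relative to the root age).
        """
        text = source
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
        seed = tree.seed_node
        # depths from root
        depth = {seed: 0.0}
        order = []
        stack = [seed]
        while stack:
            nd = stack.pop()
            order.append(nd)
            for ch in nd.child_nodes():
                bl = ch.edge.length
                if bl is None:
                    raise TreeError("Newick tree is missing branch lengths")
                depth[ch] = depth[nd] + float(bl)
                stack.append(ch)
        tips = [nd for nd in order if nd.is_leaf()]
        root_age = max(depth[t] for t in tips)
        tol = age_tolerance * max(root_age, 1.0)
        for t in tips:
            if abs(depth[t] - root_age) > tol:
                raise TreeError(
                    "tree is not ultrametric: tip "
                    f"{t.taxon.label!r} at depth {depth[t]:.6g} vs {root_age:.6g}"
                )
        labels = [t.taxon.label for t in tips]
        n_tips = len(labels)
        ids: dict = {t: i for i, t in enumerate(tips)}
        next_internal = n_tips
        for nd in order:
            if not nd.is_leaf():
                if len(nd.child_nodes()) != 2:
                    raise TreeError("polytomy in input tree; trees must be binary")
                ids[nd] = next_internal
                next_internal += 1
        n_nodes = next_internal
        parent = np.full(n_nodes, -1, dtype=np.int64)
        left = np.full(n_nodes, -1, dtype=np.int64)
        right = np.full(n_nodes, -1, dtype=np.int64)
        ages = np.zeros(n_nodes)
        for nd in order:
            i = ids[nd]
            ages[i] = 0.0 if nd.is_leaf() else root_age - depth[nd]
            if not nd.is_leaf():
                ch = nd.child_nodes()
                left[i], right[i] = ids[ch[0]], ids[ch[1]]
                parent[ids[ch[0]]] = i
                parent[ids[ch[1]]] = i
        return cls(labels, parent, left, right, ages)

    # -- basic structure --------------------------------------------------

    def _compute_postorder(self) -> np.ndarray:
        post = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if self.left[node] < 0:
                continue
            if expanded:
                post.append(node)
            else:
                stack.append((node, True))
                stack.append((int(self.right[node]), False))
                stack.append((int(self.left[node]), False))
        return np.asarray(post, dtype=np.int64)

    def validate(self) -> None:
        """Check binarity, tip ages, and strict parent-older-than-child order."""
        for i in range(self.n_nodes):
            is_tip = i < self.n_tips
            if is_tip and self.left[i] >= 0:
                raise TreeError("tip with children")
            if not is_tip and (self.left[i] < 0 or self.right[i] < 0):
                raise TreeError("internal node without two children")
        if np.any(self.ages[: self.n_tips] != 0.0):
            raise TreeError("extant tips must have age 0")
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0 and self.ages[p] <= self.ages[i]:
                raise TreeError(
                    f"parent age {self.ages[p]:.6g} not older than child "
                    f"{self.ages[i]:.6g}"
                )
        if not np.isfinite(self.ages[self.root]) or self.ages[self.root] <= 0:
            raise TreeError("root age must be finite and positive")

    def copy(self) -> "TimeTree":
        return TimeTree(self.labels, self.parent, self.left, self.right, self.ages)

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes)

    def durations(self, ages: np.ndarray | None = None) -> np.ndarray:
        """Branch durations indexed by child node (root entry 0)."""
        a = self.ages if ages is None else ages
        d = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        d[has_parent] = a[self.parent[has_parent]] - a[has_parent]
        return d

    def tip_sets(self) -> list[frozenset]:
        """Tip-label set of the clade under each node (cached)."""
        if self._tip_sets is None:
            sets: list = [None] * self.n_nodes
            for i in range(self.n_tips):
                sets[i] = frozenset((self.labels[i],))
            for node in self.postorder:
                sets[node] = sets[self.left[node]] | sets[self.right[node]]
            self._tip_sets = sets
        return self._tip_sets

    def mrca(self, labels) -> int:
        """Index of the most recent common ancestor of the given tips."""
        want = frozenset(labels)
        unknown = want - set(self.labels)
        if unknown:
            raise TreeError(f"tips not in tree: {sorted(unknown)}")
        best, best_size = self.root, self.n_tips + 1
        for node, tips in enumerate(self.tip_sets()):
            if want <= tips and len(tips) < best_size:
                best, best_size = node, len(tips)
        return best

    def node_label(self, node: int) -> str:
        """Stable human-readable node label.

        Tips keep their label; an internal node is named by the
        lexicographically smallest tip of each child subtree.
        """
        if node < self.n_tips:
            return self.labels[node]
        sets = self.tip_sets()
        return f"{min(sets[self.left[node]])}+{min(sets[self.right[node]])}"

    def extract_clade(self, labels) -> "TimeTree":
        """Subtree spanned by the MRCA of ``labels`` as its own dated tree.

        The given labels must be exactly the clade's tip set; node ages are
        preserved.
        """
        node = self.mrca(labels)
        if self.tip_sets()[node] != frozenset(labels):
            raise TreeError("labels are not a monophyletic clade of this tree")

        def build(i: int):
            if i < self.n_tips:
                return self.labels[i]
            return (
                build(int(self.left[i])),
                build(int(self.right[i])),
                float(self.ages[i]),
            )

        return TimeTree.build(build(node))

    # -- output -----------------------------------------------------------

    def to_newick(self, ages: np.ndarray | None = None, annotations=None) -> str:
        """Newick string with durations as branch lengths.

        ``annotations`` may map node index -> string rendered as an internal
        node label (e.g. posterior summaries).
        """
        a = self.ages if ages is None else ages

        def render(node: int) -> str:
            if node < self.n_tips:
                return self.labels[node]
            l, r = int(self.left[node]), int(self.right[node])
            parts = []
            for ch in (l, r):
                bl = a[node] - a[ch]
                parts.append(f"{render(ch)}:{bl:.8g}")
            label = ""
            if annotations and node in annotations:
                label = annotations[node]
            return f"({parts[0]},{parts[1]}){label}"

        return render(self.root) + ";"


def branch_expected_substitutions(parent_age: float, child_age: float, rate: float) -> float:
    """Expected substitutions/site on a branch: duration (My) times rate."""
    if parent_age < child_age:
        raise TreeError(
            f"negative branch duration: parent {parent_age} < child {child_age}"
        )
    if rate <= 0:
        raise TreeError(f"branch rate must be strictly positive, got {rate}")
    return (parent_age - child_age) * rate
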