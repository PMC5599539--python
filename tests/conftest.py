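import numpy as np
import pytest

from paleoclock.alignment import Alignment
from paleoclock.submodels import make_model
from paleoclock.timetree import TimeTree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hky_model():
    return make_model("HKY+G", kappa=4.0, freqs=(0.3, 0.2, 0.2, 0.3), alpha=0.5)


@pytest.fixture
def five_tip_tree():
    return TimeTree.build(
        (("a", "b", 2.0), (("c", "d", 1.0), "e", 3.0), 5.0)
    )


@pytest.fixture
def toy_alignment():
    return Alignment(
        ("a", "b", "c", "d", "e"),
        ("ACGTA", "ACGTT", "ACGCA", "ACGTA", "ANGTA"),
    )


def random_model(rng):
    """A random GTR-family model for property tests."""
    classes = rng.choice(["010010", "010020", "012032", "012345", "001120"])
    n_classes = len(set(classes))
    rates = (1.0,) + tuple(float(r) for r in rng.uniform(0.3, 5.0, n_classes - 1))
    freqs = rng.dirichlet([8, 8, 8, 8])
    freqs = tuple(float(f) for f in freqs / freqs.sum())
    alpha = float(rng.uniform(0.2, 3.0)) if rng.random() < 0.7 else None
    pinv = float(rng.uniform(0.0, 0.7)) if rng.random() < 0.5 else None
    return make_model(
        "custom", classes=classes, class_rates=rates, freqs=freqs,
        alpha=alpha, pinv=pinv,
    )


def random_binary_timetree(rng, n_tips, root_age=10.0):
    """Random topology with strictly ordered random node ages."""
    labels = [f"t{i}" for i in range(n_tips)]
    items = list(labels)

    def merge(lo, hi):
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        right = items.pop(j)
        left = items.pop(i)
        age = float(rng.uniform(lo, hi))
        items.append((left, right, age))
        return age

    # bottom-up: each merge strictly older than the previous
    age = 0.0
    while len(items) > 1:
        remaining = len(items) - 1
        hi = age + (root_age - age) / remaining
        age = merge(age + 1e-3, hi)
    structure = items[0]

    def set_root(node, new_age):
        return (node[0], node[1], new_age)

    return TimeTree.build(set_root(structure, root_age))
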