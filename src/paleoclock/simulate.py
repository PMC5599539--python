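"""Synthetic data generation for every pipeline stage.

Generates dated trees (a fixed eight-taxon mellitid-like demonstration shape
whose internal ages mirror the published *Encope* node ages, or Yule draws
conditioned on a root age), i.i.d. lognormal branch rates with optional
clade-specific means, forward-simulated partitioned alignments under the
+I+G models, and a complete "two-genus" bundle: two clades with identical
topology and ages whose mitochondrial partitions evolve at a 10x rate
contrast, with fossil-style calibrations at 0.8x the true node ages.  The
bundle is byte-deterministic given its seed and carries a truth file for
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, write_fasta
from .mcmc import CalibrationPrior
from .submodels import (
    ModelSpec,
    build_rate_matrix,
    make_model,
    site_rate_mixture,
    transition_probabilities,
)
from .timetree import TimeTree

BASES = "ACGT"

#: Internal ages (Ma) of the eight-taxon demonstration tree, mirroring the
#: published node ages of the Encope phylogeny.
DEMO_AGES = (15.15, 9.23, 8.11, 6.77, 5.75, 4.90, 3.88)

#: Tip name suffixes of the demonstration shape.
DEMO_TIPS = ("abe", "mich", "cal", "mic", "gra", "gal", "bor", "ema")


def demo_timetree(prefix: str = "E_", ages=None) -> TimeTree:
    """The eight-taxon demonstration tree.

    Shape: ((abe,mich) , ((cal,mic) , (gra,(gal,(bor,ema))))).  ``ages``
    optionally overrides the seven internal ages, ordered (root, split of the
    two Pacific lineages, grandis split, galapagensis split, aberrans split,
    transisthmian split, californica split).
    """
    a = tuple(float(x) for x in (ages if ages is not None else DEMO_AGES))
    if len(a) != 7:
        raise ValueError("need seven internal ages")
    root, pacific, gra, gal, abem, trans, calmic = a
    t = prefix
    structure = (
        (t + "abe", t + "mich", abem),
        (
            (t + "cal", t + "mic", calmic),
            (t + "gra", (t + "gal", (t + "bor", t + "ema", trans), gal), gra),
            pacific,
        ),
        root,
    )
    return TimeTree.build(structure)


def yule_timetree(n_tips: int, root_age: float, birth_rate: float, rng) -> TimeTree:
    """Random dated tree: Yule process conditioned on the root age.

    Conditioned on ``root_age`` the n-2 non-root node ages are i.i.d. with
    density lambda * exp(-lambda * a) / (1 - exp(-lambda * root_age)) on
    (0, root_age); the topology merges uniformly chosen lineage pairs from
    youngest age upward.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if root_age <= 0 or birth_rate <= 0:
        raise ValueError("root age and birth rate must be positive")
    u = rng.random(n_tips - 2)
    ages = -np.log1p(-u * (1.0 - math.exp(-birth_rate * root_age))) / birth_rate
    ages = np.sort(ages)
    lineages: list = [f"t{i + 1}" for i in range(n_tips)]
    for a in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        merged = (lineages[i], lineages[j], float(a))
        lineages[i] = merged
        del lineages[j]
    structure = (lineages[0], lineages[1], float(root_age))
    return TimeTree.build(structure)


def draw_branch_rates(
    tree: TimeTree,
    ucld_mean: float,
    ucld_stdev: float,
    rng,
    clade_means: dict | None = None,
) -> np.ndarray:
    """I.i.d. lognormal branch rates (indexed by child node; root entry 0).

    ``ucld_mean`` is the real-space mean and ``ucld_stdev`` the log-space
    standard deviation, so ``mu = ln(mean) - stdev^2 / 2``.  ``clade_means``
    maps a frozenset of tip labels to a mean overriding ``ucld_mean`` on
    every branch whose subtree lies inside that clade.
    """
    if ucld_mean <= 0 or ucld_stdev < 0:
        raise ValueError("ucld.mean must be positive and ucld.stdev non-negative")
    means = np.full(tree.n_nodes, float(ucld_mean))
    if clade_means:
        sets = tree.tip_sets()
        for clade, mean in clade_means.items():
            clade = frozenset(clade)
            for node in range(tree.n_nodes):
                if sets[node] <= clade:
                    means[node] = mean
    rates = np.zeros(tree.n_nodes)
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        if ucld_stdev == 0.0:
            rates[node] = means[node]
        else:
            mu = math.log(means[node]) - 0.5 * ucld_stdev**2
            rates[node] = math.exp(rng.normal(mu, ucld_stdev))
    return rates


def simulate_alignment(
    tree: TimeTree,
    branch_rates,
    model: ModelSpec,
    n_sites: int,
    rng,
) -> Alignment:
    """Forward-simulate one partition along a dated tree.

    Per-site rate classes are drawn from the model's +I+G mixture, the root
    state from the stationary frequencies, and each branch applies
    P(duration * branch rate * class rate).
    """
    rates = np.asarray(branch_rates, dtype=float)
    if rates.ndim == 0:
        rates = np.full(tree.n_nodes, float(rates))
    rm = build_rate_matrix(model)
    mixture = site_rate_mixture(model)
    cat_rates = np.array([r for r, _ in mixture])
    weights = np.array([w for _, w in mixture])
    cat = rng.choice(len(mixture), size=n_sites, p=weights)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.choice(4, size=n_sites, p=rm.pi)
    durations = tree.durations()
    preorder = [tree.root]
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for ch in (tree.left[node], tree.right[node]):
            if ch >= 0:
                preorder.append(int(ch))
                stack.append(int(ch))
    for node in preorder:
        if node == tree.root:
            continue
        parent = int(tree.parent[node])
        bl = durations[node] * rates[node]
        for ci, r in enumerate(cat_rates):
            idx = np.flatnonzero(cat == ci)
            if idx.size == 0:
                continue
            t = bl * r
            if t == 0.0:
                states[node, idx] = states[parent, idx]
                continue
            p = transition_probabilities(rm, t)
            cum = p.cumsum(axis=1)
            u = rng.random(idx.size)
            states[node, idx] = (u[:, None] > cum[states[parent, idx]]).sum(axis=1)
    seqs = tuple(
        "".join(BASES[s] for s in states[i]) for i in range(tree.n_tips)
    )
    return Alignment(tuple(tree.labels), seqs)


# -- two-genus rate-contrast scenario ------------------------------------

#: Per-gene substitution models of the five sequenced regions with the
#: published gamma shapes / invariant proportions; exchangeabilities and
#: frequencies are plausible values for echinoid mtDNA / rDNA.
def default_gene_models() -> dict[str, ModelSpec]:
    return {
        "16S": make_model("HKY+G", kappa=8.0, freqs=(0.30, 0.20, 0.20, 0.30), alpha=0.0240),
        "COI": make_model(
            "TIM3+I+G",
            class_rates=(1.0, 8.0, 1.5, 16.0),
            freqs=(0.28, 0.22, 0.20, 0.30),
            alpha=1.7370,
            pinv=0.7030,
        ),
        "ATPase8": make_model("HKY+G", kappa=8.0, freqs=(0.32, 0.20, 0.14, 0.34), alpha=0.2100),
        "ATPase6": make_model(
            "TrN+I+G",
            class_rates=(1.0, 6.0, 12.0),
            freqs=(0.30, 0.22, 0.16, 0.32),
            alpha=1.919,
            pinv=0.6500,
        ),
        "28S": make_model(
            "001120+I+F",
            class_rates=(1.0, 0.5, 3.0),
            freqs=(0.20, 0.30, 0.30, 0.20),
            pinv=0.884,
        ),
    }


#: True per-lineage clock means (substitutions/site/My) for the slow genus,
#: chosen so distance/age rates land near the published slow-genus medians
#: (a table rate of r %/My corresponds to r/200 per lineage).
SLOW_GENUS_RATES = {
    "16S": 0.0013,
    "COI": 0.0016,
    "ATPase8": 0.00245,
    "ATPase6": 0.0032,
    "28S": 5.0e-5,
}

#: Mitochondrial rate contrast of the fast genus (the nuclear gene is equal).
RATE_CONTRAST = 10.0
MITO_GENES = ("16S", "COI", "ATPase8", "ATPase6")


@dataclass
class ScenarioSpec:
    """Study conditions of the two-genus rate-contrast scenario."""

    seed: int = 1
    n_sites: dict = field(default_factory=lambda: {g: 1000 for g in ("16S", "COI", "ATPase8", "ATPase6", "28S")})
    root_age_ma: float = 20.0
    genus_ages: tuple = DEMO_AGES
    ucld_stdev: float = 0.1
    calibration_fraction: float = 0.8
    rate_contrast: float = RATE_CONTRAST


@dataclass
class TwoGenusBundle:
    """Everything the dating and rate-table stages need, plus the truth."""

    tree: TimeTree
    alignments: dict
    models: dict
    calibrations: list
    clades: dict
    truth_rates: pd.DataFrame
    spec: ScenarioSpec


def _two_genus_tree(spec: ScenarioSpec) -> TimeTree:
    structure = (
        _genus_structure("A_", spec.genus_ages),
        _genus_structure("B_", spec.genus_ages),
        spec.root_age_ma,
    )
    return TimeTree.build(structure)


def _genus_structure(prefix: str, ages):
    root, pacific, gra, gal, abem, trans, calmic = [float(x) for x in ages]
    t = prefix
    return (
        (t + "abe", t + "mich", abem),
        (
            (t + "cal", t + "mic", calmic),
            (t + "gra", (t + "gal", (t + "bor", t + "ema", trans), gal), gra),
            pacific,
        ),
        root,
    )


def make_two_genus_scenario(seed: int, spec: ScenarioSpec | None = None) -> TwoGenusBundle:
    """Generate the two-genus rate-contrast bundle (deterministic per seed)."""
    if spec is None:
        spec = ScenarioSpec(seed=seed)
    else:
        spec.seed = seed
    tree = _two_genus_tree(spec)
    models = default_gene_models()
    clade_a = frozenset(lab for lab in tree.labels if lab.startswith("A_"))
    clade_b = frozenset(lab for lab in tree.labels if lab.startswith("B_"))
    rng = np.random.default_rng([seed, 0])
    alignments = {}
    truth_rows = []
    for gene in ("16S", "COI", "ATPase8", "ATPase6", "28S"):
        slow = SLOW_GENUS_RATES[gene]
        contrast = spec.rate_contrast if gene in MITO_GENES else 1.0
        fast = slow * contrast
        rates = draw_branch_rates(
            tree,
            slow,
            spec.ucld_stdev,
            rng,
            clade_means={clade_a: slow, clade_b: fast},
        )
        alignments[gene] = simulate_alignment(
            tree, rates, models[gene], spec.n_sites[gene], rng
        )
        truth_rows.append(
            {
                "gene": gene,
                "ucld_mean_A": slow,
                "ucld_mean_B": fast,
                "rate_ratio": contrast,
                "ucld_stdev": spec.ucld_stdev,
            }
        )
    sets = tree.tip_sets()
    calibrations = []
    for name, taxa in (
        ("root", sets[tree.root]),
        ("genus_A", clade_a),
        ("genus_B", clade_b),
        ("A_transisthmian", frozenset({"A_bor", "A_ema"})),
        ("B_transisthmian", frozenset({"B_bor", "B_ema"})),
    ):
        node = tree.mrca(taxa)
        calibrations.append(
            CalibrationPrior(
                taxa=frozenset(taxa),
                offset_ma=spec.calibration_fraction * float(tree.ages[node]),
                name=name,
            )
        )
    return TwoGenusBundle(
        tree=tree,
        alignments=alignments,
        models=models,
        calibrations=calibrations,
        clades={"A": clade_a, "B": clade_b},
        truth_rates=pd.DataFrame(truth_rows),
        spec=spec,
    )


def genus_splits(tree: TimeTree, prefix: str) -> list[dict]:
    """The per-genus internal splits (label, tip groups, true age) used by
    the rate-table stage; one entry per internal node of the genus subtree."""
    sets = tree.tip_sets()
    clade = frozenset(lab for lab in tree.labels if lab.startswith(prefix))
    out = []
    for node in tree.internal_nodes:
        node = int(node)
        if not (sets[node] <= clade) or len(sets[node]) < 2:
            continue
        a = sorted(sets[tree.left[node]])
        b = sorted(sets[tree.right[node]])
        out.append(
            {
                "split": tree.node_label(node),
                "node": node,
                "group_a": a,
                "group_b": b,
                "age_ma": float(tree.ages[node]),
            }
        )
    out.sort(key=lambda r: -r["age_ma"])
    return out


def _config_text(spec: ScenarioSpec, bundle: TwoGenusBundle) -> str:
    lines = ["# two-genus rate-contrast bundle", "[input]", 'tree = "truth.nwk"', ""]
    for gene, model in bundle.models.items():
        lines += [
            "[[gene]]",
            f'name = "{gene}"',
            f'fasta = "{gene}.fasta"',
            f'model = "{model.name}"',
            f'classes = "{model.classes}"',
            f"class_rates = {list(model.class_rates)}",
            f"freqs = {list(model.freqs)}",
        ]
        if model.alpha is not None:
            lines.append(f"alpha = {model.alpha}")
        if model.pinv is not None:
            lines.append(f"pinv = {model.pinv}")
        lines.append("")
    for cal in bundle.calibrations:
        lines += [
            "[[calibration]]",
            f'name = "{cal.name}"',
            f"taxa = {sorted(cal.taxa)}",
            f"offset_ma = {cal.offset_ma}",
            "",
        ]
    for name, taxa in bundle.clades.items():
        lines += ["[[clade]]", f'name = "{name}"', f"taxa = {sorted(taxa)}", ""]
    lines += [
        "[clock]",
        "# wide mean support: the nuclear partition evolves slower than the",
        "# default lower bound",
        "mean_lower = 1e-8",
        "mean_upper = 1e100",
        "stdev_prior_mean = 0.333",
        "",
        "[mcmc]",
        "chain_length = 20000",
        "sample_interval = 20",
        "n_runs = 1",
        "burnin = 0.10",
        "thinning = 1",
        f"root_max_ma = {4 * spec.root_age_ma}",
        f"seed = {spec.seed}",
        "",
    ]
    return "\n".join(lines).replace("'", '"')


def write_bundle(bundle: TwoGenusBundle, out_dir) -> Path:
    """Write the bundle: per-gene FASTA, truth.nwk, truth_rates.tsv, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gene, aln in bundle.alignments.items():
        write_fasta(aln, out / f"{gene}.fasta")
    (out / "truth.nwk").write_text(bundle.tree.to_newick() + "\n")
    bundle.truth_rates.to_csv(out / "truth_rates.tsv", sep="\t", index=False)
    (out / "run_config.toml").write_text(_config_text(bundle.spec, bundle))
    return out
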