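"""Run configuration: one TOML file wiring alignments, tree, models, priors.

Schema (paths are resolved relative to the config file)::

    [input]
    tree = "truth.nwk"

    [[gene]]
    name = "COI"
    fasta = "COI.fasta"
    model = "TIM3+I+G"          # named model or class-string, +I/+G/+F flags
    classes = "012032"           # optional class-string override
    class_rates = [1.0, 8.0, 1.5, 16.0]   # optional; or kappa = 8.0
    freqs = "empirical"          # or four numbers
    alpha = 1.737                # gamma shape (+G)
    pinv = 0.703                 # invariant proportion (+I)

    [[calibration]]
    name = "root"
    taxa = ["A_bor", "A_ema"]
    offset_ma = 11.0
    # mean_my optional; default offset / ln(20)

    [clock]                      # optional; defaults shown
    mean_lower = 0.001
    mean_upper = 1e100
    stdev_prior_mean = 0.333

    [mcmc]
    chain_length = 100000
    sample_interval = 100
    n_runs = 1
    burnin = 0.10
    thinning = 10
    seed = 1
    root_max_ma = 1000.0

    [[clade]]                    # named tip sets for distance comparisons
    name = "A"
    taxa = ["A_abe", ...]
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import Alignment, PartitionScheme, concatenate_partitions, read_fasta
from .mcmc import CalibrationPrior, ClockPrior, ConfigurationError, McmcSettings
from .submodels import ModelSpec, empirical_frequencies, make_model
from .timetree import TimeTree


@dataclass
class LoadedRun:
    """A fully-resolved run: data, models, tree and priors."""

    config_path: Path
    config_sha256: str
    alignment: Alignment
    scheme: PartitionScheme
    models: dict[str, ModelSpec]
    tree: TimeTree
    calibrations: list[CalibrationPrior]
    clock_prior: ClockPrior
    settings: McmcSettings
    clades: dict[str, list[str]] = field(default_factory=dict)


def _build_model(gene: dict, alignment: Alignment) -> ModelSpec:
    name = gene.get("model")
    if not name:
        raise ConfigurationError(f"gene {gene.get('name')!r}: no model given")
    freqs = gene.get("freqs", "empirical")
    if freqs == "empirical":
        freqs = empirical_frequencies(alignment.seqs)
    elif isinstance(freqs, (list, tuple)) and len(freqs) == 4:
        freqs = tuple(float(f) for f in freqs)
    else:
        raise ConfigurationError(
            f"gene {gene.get('name')!r}: freqs must be \"empirical\" or four numbers"
        )
    return make_model(
        name,
        classes=gene.get("classes"),
        class_rates=gene.get("class_rates"),
        kappa=gene.get("kappa"),
        freqs=freqs,
        alpha=gene.get("alpha"),
        pinv=gene.get("pinv"),
        ncat=int(gene.get("ncat", 4)),
    )


def load_run(config_path) -> LoadedRun:
    """Parse, resolve and validate a run configuration."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw_bytes = path.read_bytes()
    cfg = tomllib.loads(raw_bytes.decode())
    base = path.parent

    tree_rel = cfg.get("input", {}).get("tree")
    if not tree_rel:
        raise ConfigurationError("config lacks [input] tree")
    tree_path = base / tree_rel
    if not tree_path.exists():
        raise ConfigurationError(f"tree file not found: {tree_path}")
    tree = TimeTree.from_newick(tree_path.read_text())

    genes = cfg.get("gene", [])
    if not genes:
        raise ConfigurationError("config lists no [[gene]] sections")
    named = []
    models = {}
    for gene in genes:
        gname = gene.get("name")
        if not gname:
            raise ConfigurationError("a [[gene]] section lacks a name")
        fasta = base / gene.get("fasta", f"{gname}.fasta")
        if not fasta.exists():
            raise ConfigurationError(f"gene {gname!r}: FASTA not found: {fasta}")
        aln = read_fasta(fasta)
        named.append((gname, aln))
        models[gname] = _build_model(gene, aln)
    alignment, scheme = concatenate_partitions(named)

    missing = set(tree.labels) - set(alignment.taxa)
    if missing:
        raise ConfigurationError(
            f"tree tips missing from alignments: {sorted(missing)}"
        )

    calibrations = []
    for cal in cfg.get("calibration", []):
        taxa = frozenset(cal.get("taxa", []))
        unknown = taxa - set(tree.labels)
        if unknown:
            raise ConfigurationError(
                f"calibration {cal.get('name', '?')!r}: unknown taxa {sorted(unknown)}"
            )
        calibrations.append(
            CalibrationPrior(
                taxa=taxa,
                offset_ma=float(cal["offset_ma"]),
                mean_my=cal.get("mean_my"),
                name=cal.get("name", ""),
            )
        )

    clock = cfg.get("clock", {})
    clock_prior = ClockPrior(
        mean_lower=float(clock.get("mean_lower", 0.001)),
        mean_upper=float(clock.get("mean_upper", 1e100)),
        stdev_prior_mean=float(clock.get("stdev_prior_mean", 0.333)),
    )

    mcmc = cfg.get("mcmc", {})
    settings = McmcSettings(
        chain_length=int(mcmc.get("chain_length", 100_000)),
        sample_interval=int(mcmc.get("sample_interval", 100)),
        n_runs=int(mcmc.get("n_runs", 1)),
        burnin=float(mcmc.get("burnin", 0.10)),
        thinning=int(mcmc.get("thinning", 10)),
        seed=int(mcmc.get("seed", 1)),
        root_max_ma=float(mcmc.get("root_max_ma", 1000.0)),
    )

    clades = {}
    for clade in cfg.get("clade", []):
        cname = clade.get("name")
        taxa = list(clade.get("taxa", []))
        unknown = set(taxa) - set(alignment.taxa)
        if unknown:
            raise ConfigurationError(
                f"clade {cname!r}: taxa not in alignments: {sorted(unknown)}"
            )
        clades[cname] = taxa

    return LoadedRun(
        config_path=path,
        config_sha256=hashlib.sha256(raw_bytes).hexdigest(),
        alignment=alignment,
        scheme=scheme,
        models=models,
        tree=tree,
        calibrations=calibrations,
        clock_prior=clock_prior,
        settings=settings,
        clades=clades,
    )
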