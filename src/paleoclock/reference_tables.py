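"""Packaged reference data for the mellitid sand-dollar study system.

Ships the published fossil-calibrated divergence table for *Encope* and for
*Mellita*/*Lanthonia* (split ages in Ma, percent distances and %/My rates per
gene), the fossil calibration offsets, and the per-gene substitution models
selected for the five sequenced regions.  These are the worked numbers the
rate statistics in :mod:`paleoclock.rates` reproduce.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .submodels import ModelSpec, make_model

#: Genes of the Encope divergence table, column order as published.
ENCOPE_GENES = ("concatenated", "16S", "COI", "ATPase8", "ATPase6", "28S")

#: Column pairs of the Mellita/Lanthonia block.  "col2" is the published
#: second distance/rate pair whose gene identity is not stated; its entries
#: are stored verbatim.
MELLITA_GENES = ("16S", "col2", "COI", "28S")

#: Published per-gene median rates (%/My) over the seven Encope splits.
ENCOPE_PUBLISHED_MEDIANS = {
    "concatenated": 0.32,
    "16S": 0.26,
    "COI": 0.32,
    "ATPase8": 0.49,
    "ATPase6": 0.64,
    "28S": 0.01,
}

#: Published per-column median rates over the eleven Mellita/Lanthonia splits.
MELLITA_PUBLISHED_MEDIANS = {
    "16S": 3.58,
    "col2": 2.32,
    "COI": 5.12,
    "28S": 0.03,
}

#: Fossil minimum ages (Ma) used as exponential-prior offsets on named clades.
FOSSIL_OFFSETS_MA = {
    "Encope": 11.0,
    "E.emarginata": 2.59,
    "E.aberrans": 2.59,
    "E.borealis": 0.78,
    "E.galapagensis": 0.78,
    "E.grandis": 0.78,
    "E.michelini": 0.78,
    "E.micropora": 0.78,
    "E.californica": 0.78,
}

#: Aligned length (bp) of each sequenced region after end trimming.
GENE_LENGTHS_BP = {
    "COI": 1296,
    "ATPase8": 168,
    "ATPase6": 687,
    "16S": 568,
    "28S": 1137,
}

#: Transisthmian *Encope* split: median age (Ma) and 95% HPD.
ENCOPE_TRANSISTHMIAN_AGE_MA = 4.90
ENCOPE_TRANSISTHMIAN_HPD_MA = (3.57, 6.54)

#: Gamma shapes / invariant proportions selected per gene (AIC model choice).
GENE_MODEL_PARAMS = {
    "16S": dict(name="HKY+G", alpha=0.0240),
    "COI": dict(name="TIM3+I+G", alpha=1.7370, pinv=0.7030),
    "ATPase6": dict(name="TrN+I+G", alpha=1.919, pinv=0.6500),
    "ATPase8": dict(name="HKY+G", alpha=0.2100),
    "28S": dict(name="001120+I+F", pinv=0.884),
}


def gene_model(gene: str, *, kappa: float = 2.0, freqs=None, class_rates=None) -> ModelSpec:
    """The selected substitution model of one gene as a :class:`ModelSpec`.

    The published model choice fixes the model family, gamma shape and
    invariant proportion; exchangeability values and base frequencies were
    estimated from the data, so they are caller-supplied (defaults: kappa 2
    for the transition classes, uniform frequencies).
    """
    try:
        params = dict(GENE_MODEL_PARAMS[gene])
    except KeyError:
        raise KeyError(f"no model recorded for gene {gene!r}") from None
    name = params.pop("name")
    return make_model(
        name, kappa=kappa, freqs=freqs, class_rates=class_rates, **params
    )


def _load(fname: str) -> pd.DataFrame:
    path = resources.files("paleoclock.data") / fname
    with path.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def encope_rate_table() -> pd.DataFrame:
    """The published Encope divergence table (7 splits)."""
    return _load("encope_rate_table.tsv")


def mellita_lanthonia_rate_table() -> pd.DataFrame:
    """The published Mellita/Lanthonia divergence table (11 splits)."""
    return _load("mellita_lanthonia_rate_table.tsv")
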