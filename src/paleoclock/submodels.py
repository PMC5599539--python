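"""Time-reversible nucleotide substitution models.

All GTR-family models are expressed through a six-digit exchangeability
class-string over the pair order (AC, AG, AT, CG, CT, GT): pairs sharing a
digit share one exchangeability parameter, and the first class is fixed to 1.
Named models (JC, HKY, TrN, TIM1-3, TPM1-3, TVM, GTR, ...) are aliases for
their class-strings, so a single constructor serves every model, including
arbitrary class-string models such as "001120".

Rate heterogeneity across sites uses the discrete-gamma approximation
(equal-weight quantile categories, each category at the conditional mean of
its gamma segment) plus an optional invariant-sites class.  The instantaneous
matrix is normalized to one expected substitution per site per unit branch
length at stationarity, and the +I+G site-rate mixture is normalized to mean
one, so branch lengths always read as expected substitutions per site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
#: Unordered base pairs in class-string order.
PAIR_ORDER = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

#: Class-strings of the named GTR-family models (jModelTest convention).
NAMED_CLASS_STRINGS = {
    "JC": "000000",
    "F81": "000000",
    "K80": "010010",
    "HKY": "010010",
    "TRNEF": "010020",
    "TRN": "010020",
    "TPM1": "012210",
    "TPM2": "010212",
    "TPM3": "012012",
    "TIM1": "012230",
    "TIM2": "010232",
    "TIM3": "012032",
    "TVM": "012314",
    "SYM": "012345",
    "GTR": "012345",
}


class ModelError(ValueError):
    """Raised for invalid substitution-model specifications."""


def _validate_class_string(classes: str) -> int:
    if not re.fullmatch(r"[0-9]{6}", classes):
        raise ModelError(f"class-string must be six digits: {classes!r}")
    digits = sorted(set(int(c) for c in classes))
    if digits != list(range(len(digits))):
        raise ModelError(
            f"class-string digits must form a contiguous set from 0: {classes!r}"
        )
    return len(digits)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one partition's substitution model.

    Parameters
    ----------
    name:
        Display name, e.g. ``"TIM3+I+G"`` or ``"001120+I+F"``.
    classes:
        Six-digit exchangeability class-string (pair order AC, AG, AT, CG,
        CT, GT).
    class_rates:
        One positive rate per exchangeability class; the first is fixed to 1.
    freqs:
        Stationary base frequencies (A, C, G, T), positive, summing to 1.
    alpha:
        Discrete-gamma shape; ``None`` disables gamma rate heterogeneity.
    pinv:
        Proportion of invariant sites in [0, 1); ``None`` disables +I.
    ncat:
        Number of discrete gamma categories.
    """

    name: str
    classes: str
    class_rates: tuple[float, ...]
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float | None = None
    pinv: float | None = None
    ncat: int = 4

    def __post_init__(self) -> None:
        n_classes = _validate_class_string(self.classes)
        if len(self.class_rates) != n_classes:
            raise ModelError(
                f"{self.name}: expected {n_classes} class rates, "
                f"got {len(self.class_rates)}"
            )
        if abs(self.class_rates[0] - 1.0) > 1e-12:
            raise ModelError(f"{self.name}: first class rate must be 1")
        if any(r <= 0 for r in self.class_rates):
            raise ModelError(f"{self.name}: class rates must be positive")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0):
            raise ModelError(f"{self.name}: need four positive frequencies")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ModelError(f"{self.name}: frequencies must sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError(f"{self.name}: gamma shape must be positive")
        if self.pinv is not None and not (0.0 <= self.pinv < 1.0):
            raise ModelError(f"{self.name}: invariant proportion must be in [0, 1)")
        if self.ncat < 1:
            raise ModelError(f"{self.name}: need at least one gamma category")

    @property
    def exchangeabilities(self) -> np.ndarray:
        """Symmetric 4x4 exchangeability matrix from the class-string."""
        s = np.zeros((4, 4))
        for (i, j), digit in zip(PAIR_ORDER, self.classes):
            s[i, j] = s[j, i] = self.class_rates[int(digit)]
        return s


def parse_model_name(name: str, allow_unknown: bool = False) -> tuple[str, bool, bool, bool]:
    """Split a model name like ``"TIM3+I+G"`` or ``"001120+I+F"``.

    Returns ``(base, plus_i, plus_g, plus_f)`` where *base* is either a named
    model or a literal class-string.  With ``allow_unknown`` an arbitrary base
    label is accepted (for custom models carrying an explicit class-string).
    """
    parts = [p.strip() for p in name.split("+")]
    base = parts[0]
    flags = {p.upper() for p in parts[1:]}
    unknown = flags - {"I", "G", "F"}
    if unknown:
        raise ModelError(f"unknown model suffix {unknown} in {name!r}")
    if base.upper() in NAMED_CLASS_STRINGS:
        base = base.upper()
    elif not re.fullmatch(r"[0-9]{6}", base) and not allow_unknown:
        raise ModelError(f"unknown model {base!r}")
    return base, "I" in flags, "G" in flags, "F" in flags


def make_model(
    name: str,
    *,
    classes: str | None = None,
    class_rates=None,
    kappa: float | None = None,
    freqs=None,
    alpha: float | None = None,
    pinv: float | None = None,
    ncat: int = 4,
) -> ModelSpec:
    """Build a :class:`ModelSpec` from a model name and parameters.

    ``kappa`` is accepted for HKY/TrN-style models as the
    transition/transversion rate ratio shared by both transition classes.
    """
    base, plus_i, plus_g, _plus_f = parse_model_name(
        name, allow_unknown=classes is not None
    )
    if classes is None:
        classes = NAMED_CLASS_STRINGS.get(base, base)
    n_classes = _validate_class_string(classes)
    if class_rates is None:
        if kappa is not None:
            class_rates = (1.0,) + (float(kappa),) * (n_classes - 1)
        else:
            class_rates = (1.0,) * n_classes
    if freqs is None:
        freqs = (0.25, 0.25, 0.25, 0.25)
    if plus_g and alpha is None:
        raise ModelError(f"{name}: +G model needs a gamma shape")
    if plus_i and pinv is None:
        raise ModelError(f"{name}: +I model needs an invariant proportion")
    return ModelSpec(
        name=name,
        classes=classes,
        class_rates=tuple(float(r) for r in class_rates),
        freqs=tuple(float(f) for f in freqs),
        alpha=alpha if plus_g or alpha is not None else None,
        pinv=pinv if plus_i or pinv is not None else None,
        ncat=ncat,
    )


def empirical_frequencies(seqs) -> tuple[float, float, float, float]:
    """Base frequencies by simple counting, ambiguities and gaps excluded."""
    counts = dict.fromkeys(BASES, 0)
    for s in seqs:
        for b in BASES:
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ModelError("no unambiguous bases for frequency estimation")
    return tuple(counts[b] / total for b in BASES)


@dataclass(frozen=True)
class RateMatrix:
    """Normalized instantaneous rate matrix with its spectral decomposition.

    ``q`` satisfies detailed balance with ``pi`` and is scaled so the expected
    substitution rate at stationarity is 1.  ``eigvals``/``right``/``left``
    give Q = right @ diag(eigvals) @ left, obtained from the symmetrized form
    so P(t) is computed stably for a reversible Q.
    """

    q: np.ndarray
    pi: np.ndarray
    scale: float
    eigvals: np.ndarray = field(repr=False, default=None)
    right: np.ndarray = field(repr=False, default=None)
    left: np.ndarray = field(repr=False, default=None)


def build_rate_matrix(spec: ModelSpec) -> RateMatrix:
    """Construct the normalized reversible Q for a model specification."""
    pi = np.asarray(spec.freqs, dtype=float)
    s = spec.exchangeabilities
    q = s * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(q)))
    if scale <= 0:
        raise ModelError(f"{spec.name}: degenerate rate matrix")
    q = q / scale
    # symmetrize: B = D^(1/2) Q D^(-1/2) is symmetric for reversible Q
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    b = 0.5 * (b + b.T)
    eigvals, v = np.linalg.eigh(b)
    right = v / d[:, None]
    left = v.T * d[None, :]
    return RateMatrix(q=q, pi=pi, scale=scale, eigvals=eigvals, right=right, left=left)


def transition_probabilities(rm: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt) by spectral decomposition; rows sum to 1, P(0) = I."""
    if t < 0:
        raise ModelError(f"negative branch length: {t}")
    if t == 0.0:
        return np.eye(4)
    p = (rm.right * np.exp(rm.eigvals * t)[None, :]) @ rm.left
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def transition_probability_tensor(rm: RateMatrix, lengths: np.ndarray) -> np.ndarray:
    """P(t) for an array of branch lengths; output shape ``lengths.shape + (4, 4)``."""
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 0):
        raise ModelError("negative branch length")
    e = np.exp(lengths[..., None] * rm.eigvals)  # (..., 4)
    p = np.einsum("ik,...k,kj->...ij", rm.right, e, rm.left)
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=-1, keepdims=True)
    p[lengths == 0.0] = np.eye(4)  # exact identity, not roundoff
    return p


def discrete_gamma_rates(alpha: float, ncat: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight discrete-gamma category rates and weights.

    Categories cut the Gamma(alpha, 1/alpha) distribution at its ``1/ncat``
    quantiles; each category rate is the conditional mean of its segment, so
    the weighted mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if ncat < 1:
        raise ModelError("need at least one gamma category")
    if ncat == 1:
        return np.array([1.0]), np.array([1.0])
    probs = np.arange(1, ncat) / ncat
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    # E[X; segment] with X ~ Gamma(a, 1/a): integral of x f(x) over the segment
    # equals the Gamma(a+1, 1/a) probability of the segment (mean 1).
    upper = gamma_dist.cdf(cuts, a=alpha + 1.0, scale=1.0 / alpha)
    seg = np.diff(np.concatenate([[0.0], upper, [1.0]]))
    rates = seg * ncat
    rates /= rates.mean()  # absorb roundoff so the mean is exactly 1
    weights = np.full(ncat, 1.0 / ncat)
    return rates, weights


def site_rate_mixture(spec: ModelSpec) -> list[tuple[float, float]]:
    """Site-rate classes (rate, weight) including the invariant class.

    The invariant class has rate 0 and weight ``pinv``; gamma categories carry
    weight ``(1 - pinv)/ncat`` and rates rescaled by ``1/(1 - pinv)`` so the
    mixture mean is exactly 1.
    """
    pinv = spec.pinv or 0.0
    if spec.alpha is not None:
        rates, weights = discrete_gamma_rates(spec.alpha, spec.ncat)
    else:
        rates, weights = np.array([1.0]), np.array([1.0])
    classes: list[tuple[float, float]] = []
    if pinv > 0:
        classes.append((0.0, pinv))
    scale = 1.0 / (1.0 - pinv)
    classes.extend(
        (float(r * scale), float(w * (1.0 - pinv))) for r, w in zip(rates, weights)
    )
    return classes
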