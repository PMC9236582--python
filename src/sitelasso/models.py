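"""Reversible substitution models and discrete-gamma rate heterogeneity.

Supports the empirical amino-acid replacement models WAG, JTT and LG (published
exchangeabilities and stationary frequencies embedded as plain-text data files)
and the nucleotide GTR family. A rate matrix is assembled as Q = S diag(pi) with
the diagonal set for zero row sums and the whole matrix rescaled so that the
mean substitution rate -sum_i pi_i Q_ii equals 1, keeping branch lengths in
expected-substitutions-per-site units.

Among-site rate variation follows the discrete-gamma model: k equal-probability
categories whose rates are the conditional means of the Gamma(alpha, alpha)
quantile slices, renormalized to average exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .errors import ValidationError
from .msa_io import AA_STATES, DNA_STATES, ambiguity_map, states_for

_EMPIRICAL_FILES = {"WAG": "wag.txt", "JTT": "jtt.txt", "LG": "lg.txt"}


def load_empirical_matrix(name: str):
    """Load a published amino-acid model: (exchangeabilities S, frequencies pi).

    Rows/columns follow the standard order ``ARNDCQEGHILKMFPSTWYV``.
    """
    fname = _EMPIRICAL_FILES[name.upper()]
    text = resources.files("sitelasso.data").joinpath(fname).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    order = "".join(lines[0].split())
    S = np.array([[float(x) for x in ln.split()] for ln in lines[1:21]])
    pi = np.array([float(x) for x in lines[21].split()])
    if order != AA_STATES:  # data files are written in canonical order already
        perm = [order.index(c) for c in AA_STATES]
        S = S[np.ix_(perm, perm)]
        pi = pi[perm]
    return S, pi / pi.sum()


@dataclass
class GammaCategories:
    """Equal-probability discrete-gamma rate categories."""

    rates: np.ndarray
    probabilities: np.ndarray

    @property
    def k(self) -> int:
        return len(self.rates)


def discretize_gamma(alpha: float, k: int) -> GammaCategories:
    """Discretize a Gamma(alpha, alpha) rate distribution into k categories.

    Each category has probability 1/k and rate equal to the mean of its
    quantile slice (the Yang-1994 mean method), using the identity
    E[X; X<x] = F_{alpha+1}(x) for X ~ Gamma(alpha, rate alpha). The rates are
    renormalized post hoc so their mean is exactly 1.
    """
    if alpha <= 0:
        raise ValidationError("gamma shape alpha must be > 0")
    if k < 1:
        raise ValidationError("need at least one rate category")
    if k == 1:
        return GammaCategories(np.array([1.0]), np.array([1.0]))
    cuts = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1, alpha * cuts)  # partial expectations at the cuts
    cdf_plus = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cdf_plus)
    rates = rates / rates.mean()
    return GammaCategories(rates, np.full(k, 1.0 / k))


@dataclass
class SubstitutionModel:
    """A reversible substitution model with optional gamma rate heterogeneity.

    Attributes with a trailing role: ``exchangeabilities`` (symmetric S, zero
    diagonal), ``frequencies`` (stationary pi), ``Q`` (unit-mean-rate matrix),
    ``alpha``/``n_categories`` (gamma model; ``alpha=None`` means rate homogeneity).
    """

    name: str
    alphabet: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    n_categories: int = 4
    Q: np.ndarray = field(init=False)
    _eigen: tuple = field(init=False, repr=False)

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.frequencies, float)
        n = len(states_for(self.alphabet))
        if S.shape != (n, n):
            raise ValidationError(f"exchangeability matrix must be {n}x{n}")
        if not np.allclose(S, S.T):
            raise ValidationError("exchangeability matrix must be symmetric")
        if (S < 0).any():
            raise ValidationError("exchangeabilities must be non-negative")
        if pi.shape != (n,):
            raise ValidationError(f"frequency vector must have length {n}")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ValidationError("frequencies must sum to 1 (tol 1e-6)")
        if (pi <= 0).any():
            raise ValidationError("all stationary frequencies must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        if mu <= 0:
            raise ValidationError("degenerate rate matrix (zero mean rate)")
        Q /= mu
        self.exchangeabilities = S
        self.frequencies = pi
        self.Q = Q
        # Symmetric similarity transform of the reversible Q: B = D Q D^-1 with
        # D = diag(sqrt(pi)) is symmetric, so eigh applies and P(t) is exact.
        sq = np.sqrt(pi)
        B = Q * (sq[:, None] / sq[None, :])
        B = 0.5 * (B + B.T)
        evals, V = np.linalg.eigh(B)
        left = V.T * sq[None, :]        # rows of V^T D
        right = (V.T / sq[None, :]).T   # D^-1 V
        self._eigen = (evals, right, left)

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def gamma_categories(self) -> GammaCategories:
        if self.alpha is None or self.n_categories == 1:
            return GammaCategories(np.array([1.0]), np.array([1.0]))
        return discretize_gamma(self.alpha, self.n_categories)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return SubstitutionModel(
            self.name, self.alphabet, self.exchangeabilities, self.frequencies,
            alpha=alpha, n_categories=self.n_categories,
        )

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q t rate); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValidationError("branch length must be >= 0")
        evals, right, left = self._eigen
        P = (right * np.exp(evals * t * rate)[None, :]) @ left
        return np.maximum(P, 0.0)

    def transition_stack(self, t: float, rates: np.ndarray) -> np.ndarray:
        """(k, n, n) stack of P(t * r_c) over rate categories."""
        if t < 0:
            raise ValidationError("branch length must be >= 0")
        evals, right, left = self._eigen
        expo = np.exp(evals[None, :] * (t * np.asarray(rates))[:, None])  # (k, n)
        P = np.einsum("ie,ke,ej->kij", right, expo, left)
        return np.maximum(P, 0.0)


def transition_probabilities(model: SubstitutionModel, t: float, rate: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate)


def empirical_frequencies(aln, pseudocount: float = 1.0) -> np.ndarray:
    """Observed residue frequencies with add-one (Laplace) pseudocounts.

    Ambiguity codes contribute fractionally to each compatible state.
    """
    states = states_for(aln.alphabet)
    amb = ambiguity_map(aln.alphabet)
    counts = np.full(len(states), pseudocount, float)
    chars, char_counts = np.unique(aln.matrix, return_counts=True)
    for ch, c in zip(chars, char_counts):
        compat = amb[ch]
        if len(compat) == len(states):
            continue  # fully ambiguous carries no information
        w = c / len(compat)
        for s in compat:
            counts[states.index(s)] += w
    return counts / counts.sum()


def _parse_spec(spec: str):
    """Split a model string like ``WAG+G4+F`` into (name, n_cat or None, plus_f)."""
    parts = spec.strip().split("+")
    name = parts[0].upper()
    n_cat = None
    plus_f = False
    for p in parts[1:]:
        p = p.upper()
        if p.startswith("G"):
            n_cat = int(p[1:]) if len(p) > 1 else 4
        elif p == "F":
            plus_f = True
        else:
            raise ValidationError(f"unrecognized model suffix +{p}")
    return name, n_cat, plus_f


def build_model(
    name: str,
    frequencies: str | np.ndarray = "model",
    exchangeabilities=None,
    alpha: float | None = None,
    n_categories: int | None = None,
    alignment=None,
) -> SubstitutionModel:
    """Build a substitution model.

    Parameters
    ----------
    name : str
        ``WAG``, ``JTT``, ``LG`` or ``GTR``, optionally with suffixes as a spec
        string (``"WAG+G4"``, ``"LG+G4+F"``, ``"GTR+G"``). ``+G`` turns on
        gamma heterogeneity (alpha defaults to 1.0 if not given), ``+F`` uses
        empirical frequencies counted from ``alignment``.
    frequencies : {"model", "empirical"} or array
        Source of stationary frequencies. ``"model"`` uses the published values
        (uniform for GTR unless given).
    exchangeabilities : array, optional
        Six upper-triangle values (order AC, AG, AT, CG, CT, GT) or a full
        symmetric matrix; required meaningfully only for GTR (default: all 1,
        i.e. Jukes-Cantor-like when frequencies are uniform).
    """
    base, spec_cat, plus_f = _parse_spec(name)
    if spec_cat is not None and n_categories is None:
        n_categories = spec_cat
        if alpha is None:
            alpha = 1.0
    if n_categories is None:
        n_categories = 4 if alpha is not None else 1
    if plus_f:
        frequencies = "empirical"

    if base in _EMPIRICAL_FILES:
        S, pi_model = load_empirical_matrix(base)
        alphabet = "aa"
    elif base == "GTR":
        alphabet = "dna"
        if exchangeabilities is None:
            S = np.ones((4, 4))
        else:
            ex = np.asarray(exchangeabilities, float)
            if ex.shape == (6,):
                S = np.zeros((4, 4))
                S[np.triu_indices(4, 1)] = ex
                S = S + S.T
            else:
                S = ex
        np.fill_diagonal(S, 0.0)
        pi_model = np.full(4, 0.25)
    else:
        raise ValidationError(f"unknown model {base!r}")
    np.fill_diagonal(S, 0.0)

    if isinstance(frequencies, str):
        if frequencies == "model":
            pi = pi_model
        elif frequencies == "empirical":
            if alignment is None:
                raise ValidationError("empirical frequencies require an alignment")
            pi = empirical_frequencies(alignment)
        else:
            raise ValidationError(f"unknown frequency mode {frequencies!r}")
    else:
        pi = np.asarray(frequencies, float)

    return SubstitutionModel(base, alphabet, S, pi, alpha=alpha, n_categories=n_categories)


def jukes_cantor(alpha: float | None = None, n_categories: int = 1) -> SubstitutionModel:
    """The Jukes-Cantor model: GTR with equal exchangeabilities and uniform pi."""
    return build_model("GTR", alpha=alpha, n_categories=n_categories)


DNA_ALPHABET = DNA_STATES  # re-export for convenience
AA_ALPHABET = AA_STATES
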