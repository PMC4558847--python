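"""Reversible substitution models with discrete-Γ rate heterogeneity.

Models are parameterized the standard way: an instantaneous rate matrix
``Q`` built from symmetric exchangeabilities ``r_xy`` and stationary
frequencies ``π`` as ``Q_xy = r_xy * π_y`` (x ≠ y), with the diagonal set so
rows sum to zero and the whole matrix rescaled so that the expected
substitution rate at stationarity, ``-Σ_x π_x Q_xx``, equals one.  Branch
lengths are then in expected substitutions per site.

Among-site rate variation uses Yang's discrete-Γ approximation: ``ncat``
equal-probability categories, each represented by the mean of the Γ(α, α)
distribution over its quantile interval, so the category rates average one.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma

NT_ALPHABET = "ACGT"
#: PAML ordering, as used by the bundled empirical matrices.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Order of the six GTR exchangeabilities: (AC, AG, AT, CG, CT, GT).
GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

# GTR+Γ nucleotide parameterization used throughout the simulation study
# (mammalian-gene-inspired values; r_AG = 1 convention).
STUDY_GTR_EXCHANGEABILITIES = (0.30, 1.0, 0.20, 0.25, 1.39, 0.22)
STUDY_GTR_FREQUENCIES = (0.25, 0.26, 0.27, 0.22)
STUDY_GAMMA_SHAPE = 1.8


class ParameterError(ValueError):
    """A model parameter is outside its domain."""


class UnsupportedModelError(ValueError):
    """Unknown empirical model name."""


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible substitution model.

    Attributes
    ----------
    alphabet : str
        Ordered state characters (4 nt or 20 aa).
    exchangeabilities : ndarray
        Symmetric (s, s) matrix of r_xy with zero diagonal.
    frequencies : ndarray
        Stationary distribution π (sums to 1).
    """

    alphabet: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    rate_matrix: np.ndarray = field(init=False, repr=False)
    _eigen: tuple = field(init=False, repr=False)

    def __post_init__(self):
        s = len(self.alphabet)
        r = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if r.shape != (s, s) or not np.allclose(r, r.T):
            raise ParameterError("exchangeabilities must be a symmetric (s, s) matrix")
        if np.any(r[~np.eye(s, dtype=bool)] <= 0):
            raise ParameterError("exchangeabilities must be positive")
        if np.any(pi <= 0):
            raise ParameterError("frequencies must be positive")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ParameterError("frequencies must sum to 1 (within 1e-6)")
        pi = pi / pi.sum()
        Q = r * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q = Q / mu
        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "exchangeabilities", r)
        object.__setattr__(self, "rate_matrix", Q)
        # Symmetric eigendecomposition of B = Π^{1/2} Q Π^{-1/2}: numerically
        # stable matrix exponentials for reversible Q.
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        w, V = np.linalg.eigh(B)
        left = V.T * sq[None, :]        # V^T Π^{1/2}
        right = V / sq[:, None]         # Π^{-1/2} V
        object.__setattr__(self, "_eigen", (w, right, left))

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def with_frequencies(self, frequencies) -> "SubstitutionModel":
        """Same exchangeabilities, new stationary frequencies (+F usage)."""
        return SubstitutionModel(self.alphabet, self.exchangeabilities, frequencies)

    def transition_probs(self, branch_length: float, rate: float = 1.0) -> np.ndarray:
        """P(t·rate) = exp(Q t rate); rows sum to one."""
        return transition_probs(self, branch_length, rate)


@dataclass(frozen=True)
class GammaRates:
    """Discrete-Γ among-site rate categories (equal probability, mean 1)."""

    shape: float
    ncat: int
    category_rates: np.ndarray
    category_probs: np.ndarray


def build_gtr(exchangeabilities, frequencies) -> SubstitutionModel:
    """Construct a GTR nucleotide model.

    Parameters are the six exchangeabilities in (AC, AG, AT, CG, CT, GT)
    order and the four stationary frequencies (A, C, G, T).  The stored
    exchangeabilities are normalized relative to r_AG = 1.
    """
    r6 = np.asarray(exchangeabilities, dtype=float)
    if r6.shape != (6,):
        raise ParameterError("expected six exchangeabilities (AC, AG, AT, CG, CT, GT)")
    if np.any(r6 <= 0):
        raise ParameterError("exchangeabilities must be positive")
    r6 = r6 / r6[1]  # r_AG = 1 convention
    R = np.zeros((4, 4))
    for val, (i, j) in zip(r6, GTR_PAIRS):
        R[i, j] = R[j, i] = val
    return SubstitutionModel(NT_ALPHABET, R, frequencies)


def study_gtr_model() -> SubstitutionModel:
    """The study's GTR nucleotide model (rCT = 1.39 etc.)."""
    return build_gtr(STUDY_GTR_EXCHANGEABILITIES, STUDY_GTR_FREQUENCIES)


def _load_wag():
    text = (
        importlib.resources.files("msabias.data").joinpath("wag.dat").read_text()
    )
    rows = [
        [float(tok) for tok in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    R = np.zeros((20, 20))
    for i, vals in enumerate(rows[:19], start=1):
        R[i, : len(vals)] = vals
    R = R + R.T
    freqs = np.asarray(rows[19])
    return R, freqs


def build_empirical_aa(name: str = "WAG", frequencies=None) -> SubstitutionModel:
    """Construct an empirical amino-acid model (currently WAG).

    With ``frequencies=None`` the model's published stationary frequencies
    are used; supplying observed-count frequencies gives the +F variant.
    """
    if name.upper() != "WAG":
        raise UnsupportedModelError(f"unsupported empirical model: {name!r}")
    R, default_freqs = _load_wag()
    pi = default_freqs if frequencies is None else np.asarray(frequencies, float)
    return SubstitutionModel(AA_ALPHABET, R, pi)


def discretize_gamma(shape: float, ncat: int = 4) -> GammaRates:
    """Discrete-Γ rates: equal-probability categories with interval means.

    For ``X ~ Γ(α, rate=α)`` (mean 1) split into ``ncat`` quantile intervals,
    the category rate is ``E[X | X in interval]``, computed in closed form
    via the incomplete-gamma identity
    ``∫ x f_α(x) dx = F_{α+1}(b) − F_{α+1}(a)`` (scaled).
    """
    if shape <= 0:
        raise ParameterError("gamma shape must be positive")
    if ncat < 1:
        raise ParameterError("ncat must be >= 1")
    probs = np.full(ncat, 1.0 / ncat)
    if ncat == 1:
        return GammaRates(shape, 1, np.array([1.0]), probs)
    edges = _gamma.ppf(np.linspace(0, 1, ncat + 1), a=shape, scale=1.0 / shape)
    upper = _gamma.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = (upper[1:] - upper[:-1]) * ncat
    rates = rates / (rates * probs).sum()  # exact mean 1
    return GammaRates(shape, ncat, rates, probs)


def transition_probs(
    model: SubstitutionModel, branch_length: float, rate: float = 1.0
) -> np.ndarray:
    """Transition matrix P(branch_length · rate) for a reversible model."""
    if branch_length < 0:
        raise ParameterError("branch length must be non-negative")
    if rate <= 0:
        raise ParameterError("rate must be positive")
    if branch_length == 0:
        return np.eye(model.n_states)
    w, right, left = model._eigen
    P = (right * np.exp(w * branch_length * rate)[None, :]) @ left
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
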