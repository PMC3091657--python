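"""Empirical amino-acid substitution models with discrete-Gamma rates.

A model couples a symmetric exchangeability matrix S with equilibrium
frequencies pi into the reversible rate matrix

    Q_ij = c * S_ij * pi_j   (i != j),      Q_ii = -sum_{j!=i} Q_ij,

with c chosen so that -sum_i pi_i Q_ii = 1, i.e. branch lengths are in
expected substitutions per site.  Among-site rate heterogeneity uses the
discrete-Gamma approximation: K equal-probability categories whose rates
are the category means of a Gamma(alpha, alpha) distribution,
renormalized to mean exactly 1.

The four shipped matrices (WAG, RtREV, cpREV, Blosum62) are the
published values, stored as plain-text lower triangles plus frequencies
under ``data/``.  Blosum62 is used here in its rate-matrix
(exchangeability) form as distributed by phylogenetics engines, not as a
log-odds scoring matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .alphabet import N_STATES

EMPIRICAL_MODELS = ("WAG", "RTREV", "CPREV", "BLOSUM62")

_MIN_RATE = 1e-8  # floor for discrete rates at extreme alpha


class ModelError(ValueError):
    pass


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Assemble the normalized reversible rate matrix from S and pi."""
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ModelError(f"exchangeability matrix must be 20x20, got {S.shape}")
    if not np.allclose(S, S.T):
        raise ModelError("exchangeability matrix must be symmetric")
    if np.any(S[~np.eye(N_STATES, dtype=bool)] < 0):
        raise ModelError("exchangeabilities must be non-negative")
    if pi.shape != (N_STATES,) or not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ModelError("frequencies must be a length-20 distribution")
    if np.any(pi <= 0):
        raise ModelError("equilibrium frequencies must be strictly positive")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    return Q / scale


def discretize_gamma(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-per-quantile discrete Gamma rates (K categories, mean 1).

    Category i covers the probability interval [i/k, (i+1)/k] of
    Gamma(alpha, rate=alpha); its rate is the conditional mean over that
    interval, obtained from the incomplete-Gamma identity
    E[X; X<u] = F_{alpha+1}(u) for a mean-1 Gamma.  Rates are
    renormalized so their mean is exactly 1.
    """
    if alpha <= 0:
        raise ModelError(f"Gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    upper_cdf = _gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper_cdf)
    rates = np.maximum(rates, _MIN_RATE)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible amino-acid model plus its spectral decomposition.

    The eigendecomposition of the pi-symmetrized rate matrix is done
    once per model; P(t) for any branch/rate is then assembled from it.
    """

    name: str
    S: np.ndarray
    pi: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    Q: np.ndarray = field(init=False, repr=False)
    rates: np.ndarray = field(init=False, repr=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        Q = build_rate_matrix(self.S, self.pi)
        sqrt_pi = np.sqrt(self.pi)
        B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)  # kill rounding asymmetry
        w, V = np.linalg.eigh(B)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "rates", discretize_gamma(self.alpha, self.n_categories))
        object.__setattr__(self, "_eigvals", w)
        # P(t) = right @ diag(exp(w t)) @ left
        object.__setattr__(self, "_right", V / sqrt_pi[:, None])
        object.__setattr__(self, "_left", V.T * sqrt_pi[None, :])

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return replace(self, alpha=alpha)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t) = exp(Q rate t); rows sum to 1, entries clamped >= 0."""
        if t < 0:
            raise ModelError(f"branch length must be non-negative, got {t}")
        P = (self._right * np.exp(self._eigvals * (rate * t))) @ self._left
        if P.min() < -1e-12:
            # eigensolver noise only; anything larger is a real defect
            raise ModelError("transition matrix has significantly negative entries")
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(r_k * t) over the K discrete-Gamma categories."""
        if t < 0:
            raise ModelError(f"branch length must be non-negative, got {t}")
        expo = np.exp(self._eigvals[None, :] * (self.rates * t)[:, None])  # (K, 20)
        P = (self._right[None, :, :] * expo[:, None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P


def _parse_model_file(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = [ln.split() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(rows) != N_STATES:
        raise ModelError(f"model file must have 19 triangle rows + frequencies, got {len(rows)} rows")
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(rows[:-1], start=1):
        if len(row) != i:
            raise ModelError(f"triangle row {i} has {len(row)} entries, expected {i}")
        S[i, :i] = [float(x) for x in row]
    S = S + S.T
    pi = np.array([float(x) for x in rows[-1]])
    return S, pi / pi.sum()


def load_empirical_model(name: str, alpha: float = 1.0, n_categories: int = 4) -> SubstitutionModel:
    """Load one of the shipped empirical models by name (case-insensitive)."""
    key = name.upper()
    if key not in EMPIRICAL_MODELS:
        raise ModelError(
            f"unknown substitution model {name!r}; available: {', '.join(EMPIRICAL_MODELS)}"
        )
    text = resources.files("phyloplace.data").joinpath(f"{key.lower()}.dat").read_text()
    S, pi = _parse_model_file(text)
    return SubstitutionModel(name=key, S=S, pi=pi, alpha=alpha, n_categories=n_categories)


def uniform_model(alpha: float = 1.0, n_categories: int = 1) -> SubstitutionModel:
    """Equal-rates model (all exchangeabilities equal, uniform frequencies).

    Under this model P(t) has the closed form
    p_ii = e^{-beta t} + (1 - e^{-beta t})/20, p_ij = (1 - e^{-beta t})/20
    with beta = 20/19, which several tests exploit.
    """
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return SubstitutionModel(name="UNIFORM", S=S, pi=pi, alpha=alpha, n_categories=n_categories)


#: Rate of leaving any state in the uniform model (from the normalization).
UNIFORM_BETA = 20.0 / 19.0
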