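"""Substitution models: binary CTMC, binary covarion, HKY, Gamma site rates.

All generators are normalized so that one unit of branch length equals one
expected substitution per character at rate 1.  For the covarion model only
*visible* 0<->1 changes count towards that expectation — hidden ON/OFF
switches are free — matching the convention of the standard binary covarion
used in Bayesian language phylogenetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "BinaryCTMCParams", "CovarionParams", "HKYParams", "SiteRateModel",
    "RateMatrix", "build_rate_matrix", "transition_matrix",
    "transition_matrices", "gamma_category_rates",
]


@dataclass(frozen=True)
class BinaryCTMCParams:
    """Two-state reversible CTMC with stationary frequencies (pi0, pi1)."""
    pi0: float = 0.5
    pi1: float = 0.5
    rate: float = 1.0

    def __post_init__(self):
        if self.pi0 <= 0 or self.pi1 <= 0:
            raise ValueError("stationary frequencies must be positive")
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-9:
            raise ValueError("pi0 + pi1 must equal 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass(frozen=True)
class CovarionParams:
    """Binary covarion: a visible 0/1 chain gated by a hidden ON/OFF switch.

    The expanded state space is (0/ON, 1/ON, 0/OFF, 1/OFF); visible change
    happens only while ON, and the hidden switch runs at overall rate ``s``
    towards stationary ON/OFF frequencies ``hidden_freqs``.
    """
    visible: BinaryCTMCParams = field(default_factory=BinaryCTMCParams)
    s: float = 0.5
    hidden_freqs: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("switch rate s must be >= 0")
        f_on, f_off = self.hidden_freqs
        if f_on < 0 or f_off < 0 or abs(f_on + f_off - 1.0) > 1e-9:
            raise ValueError("hidden_freqs must be non-negative and sum to 1")
        if f_on == 0:
            raise ValueError("hidden ON frequency must be positive")


@dataclass(frozen=True)
class HKYParams:
    """HKY85 nucleotide model (transition/transversion ratio kappa)."""
    kappa: float = 2.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rate: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0 or self.rate <= 0:
            raise ValueError("kappa and rate must be positive")
        f = np.asarray(self.freqs)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be positive and sum to 1")


@dataclass(frozen=True)
class SiteRateModel:
    """Across-site rate heterogeneity: 1 category or 4 equal-weight Gamma
    categories at category means (shape ``shape``, mean 1)."""
    ncat: int = 1
    shape: float = 1.0

    def __post_init__(self):
        if self.ncat not in (1, 4):
            raise ValueError("ncat must be 1 or 4")
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")

    def rates(self) -> np.ndarray:
        if self.ncat == 1:
            return np.ones(1)
        return gamma_category_rates(self.shape, self.ncat)


def gamma_category_rates(shape: float, ncat: int) -> np.ndarray:
    """Means of ``ncat`` equal-probability slices of Gamma(shape, mean 1)."""
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=shape,
                           scale=1.0 / shape)
    # E[X | a < X <= b] * P = gammainc(shape+1, shape*b) - gammainc(shape+1, shape*a)
    upper = gammainc(shape + 1, shape * edges[1:])
    lower = gammainc(shape + 1, shape * np.concatenate([[0.0], edges[1:-1]]))
    return ncat * (upper - lower)


class RateMatrix:
    """A normalized generator plus the bookkeeping pruning needs.

    Attributes
    ----------
    Q : (k, k) generator, rows sum to 0
    freqs : stationary distribution of Q
    tip_partials : mapping observed symbol -> conditional-likelihood vector
        over the k model states (covarion tips spread over hidden states;
        missing data maps to all-ones)
    """

    def __init__(self, Q: np.ndarray, freqs: np.ndarray,
                 tip_partials: dict):
        self.Q = np.asarray(Q, dtype=float)
        self.freqs = np.asarray(freqs, dtype=float)
        self.tip_partials = tip_partials
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-9):
            raise ValueError("generator rows must sum to 0")
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if np.max(np.abs(self.freqs @ self.Q)) > 1e-8:
            raise ValueError("declared frequencies are not stationary")
        self._eig = None

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def _eigendecompose(self):
        if self._eig is None:
            w, v = np.linalg.eig(self.Q)
            try:
                vinv = np.linalg.inv(v)
                ill = np.linalg.cond(v) > 1e8
            except np.linalg.LinAlgError:
                vinv, ill = None, True
            self._eig = (w, v, vinv, ill)
        return self._eig


_BIN_TIPS = {1: np.array([0.0, 1.0]), 0: np.array([1.0, 0.0]),
             -1: np.array([1.0, 1.0])}
_COV_TIPS = {1: np.array([0.0, 1.0, 0.0, 1.0]),
             0: np.array([1.0, 0.0, 1.0, 0.0]),
             -1: np.ones(4)}
_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _nuc_tips() -> dict:
    tips = {}
    for b, i in _NUC_INDEX.items():
        v = np.zeros(4)
        v[i] = 1.0
        tips[b] = v
    for amb in ("N", "?", "-"):
        tips[amb] = np.ones(4)
    tips["R"] = np.array([1.0, 0, 1.0, 0])
    tips["Y"] = np.array([0, 1.0, 0, 1.0])
    return tips


def build_rate_matrix(model) -> RateMatrix:
    """Build the normalized generator for a site model parameter bundle."""
    if isinstance(model, BinaryCTMCParams):
        pi = np.array([model.pi0, model.pi1])
        Q = np.array([[-pi[1], pi[1]], [pi[0], -pi[0]]], dtype=float)
        flux = 2 * pi[0] * pi[1]          # expected substitutions at rate 1
        Q = Q / flux * model.rate
        return RateMatrix(Q, pi, dict(_BIN_TIPS))

    if isinstance(model, CovarionParams):
        vis = model.visible
        pi = np.array([vis.pi0, vis.pi1])
        f_on, f_off = model.hidden_freqs
        k = 4
        Q = np.zeros((k, k))
        # visible changes while ON (states 0=0/ON, 1=1/ON)
        Q[0, 1] = pi[1]
        Q[1, 0] = pi[0]
        # hidden switching at overall rate s, stationary (f_on, f_off)
        Q[0, 2] = Q[1, 3] = model.s * f_off
        Q[2, 0] = Q[3, 1] = model.s * f_on
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        freqs = np.array([pi[0] * f_on, pi[1] * f_on,
                          pi[0] * f_off, pi[1] * f_off])
        # count visible changes only; at s == 0 the hidden chain is frozen
        # ON, so the visible flux is unweighted
        vis_flux = 2 * pi[0] * pi[1] * (f_on if model.s > 0 else 1.0)
        Q = Q / vis_flux * vis.rate
        if model.s == 0:
            freqs = np.array([pi[0], pi[1], 0.0, 0.0])
        return RateMatrix(Q, freqs, dict(_COV_TIPS))

    if isinstance(model, HKYParams):
        f = np.asarray(model.freqs)
        k = model.kappa
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}   # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i != j:
                    Q[i, j] = f[j] * (k if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        flux = -np.sum(f * np.diag(Q))
        Q = Q / flux * model.rate
        return RateMatrix(Q, f, _nuc_tips())

    raise TypeError(f"unsupported model type {type(model).__name__}")


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1."""
    if t < 0:
        raise ValueError("duration must be non-negative")
    P = scipy.linalg.expm(rm.Q * t)
    return np.clip(P, 0.0, None)


def transition_matrices(rm, ts: np.ndarray) -> np.ndarray:
    """Batched P(t) for many durations via one eigendecomposition.

    ``rm`` may be a :class:`RateMatrix` or a plain generator matrix.
    Returns an array of shape ``(len(ts), k, k)``; falls back to expm when
    the eigenbasis is ill-conditioned.
    """
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("durations must be non-negative")
    Q = rm.Q if hasattr(rm, "Q") else np.asarray(rm, dtype=float)
    if hasattr(rm, "_eigendecompose"):
        w, v, vinv, ill = rm._eigendecompose()
    else:
        w, v = np.linalg.eig(Q)
        try:
            vinv = np.linalg.inv(v)
            ill = np.linalg.cond(v) > 1e8
        except np.linalg.LinAlgError:
            vinv, ill = None, True
    if ill:                         # defective or near-defective generator
        return np.stack([np.clip(scipy.linalg.expm(Q * t), 0.0, None)
                         for t in ts])
    E = np.exp(np.multiply.outer(ts, w))          # (m, k)
    P = np.einsum("jk,mk,kl->mjl", v, E, vinv)
    P = np.real(P)
    return np.clip(P, 0.0, None)
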