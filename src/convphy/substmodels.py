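"""Amino-acid substitution models with discrete-Gamma rate heterogeneity.

Implements the empirical JTT and WAG replacement models as reversible
rate matrices, the Yang (1994) discrete-Gamma approximation to
among-site rate variation (category means over equal-probability bins),
and transition probabilities P(t) = exp(Qt) via eigendecomposition of
the symmetrized generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from . import _aa_data
from .alignment import MISSING, Alignment

ALPHA_BOUNDS = (0.02, 100.0)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Rate multipliers for k equal-weight categories of a Gamma(alpha, alpha).

    Categories are the means of k equal-probability bins of the
    Gamma(shape=alpha, rate=alpha) distribution, normalized to mean 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"category count must be >= 1, got {k}")
    if k == 1:
        return np.ones(1)
    dist = stats.gamma(a=alpha, scale=1.0 / alpha)
    edges = dist.ppf(np.linspace(0.0, 1.0, k + 1))
    # mean of a Gamma(a, 1/a) over [lo, hi) equals the Gamma(a+1, 1/a) mass
    # in the same bin divided by the bin probability (a standard identity)
    dist1 = stats.gamma(a=alpha + 1.0, scale=1.0 / alpha)
    mass = np.diff(dist1.cdf(edges))
    rates = mass * k
    return rates / rates.mean()


def _build_reversible_q(exchange: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Assemble and scale a reversible generator from exchangeabilities."""
    n = len(pi)
    s = np.zeros((n, n))
    s[np.triu_indices(n, 1)] = exchange
    s = s + s.T
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    return q / scale


@dataclass
class EigenQ:
    """Eigendecomposition of a reversible generator, for fast P(t)."""

    pi: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray       # U such that Q = U diag(evals) U^{-1}
    inv_evecs: np.ndarray

    @classmethod
    def from_q(cls, q: np.ndarray, pi: np.ndarray) -> "EigenQ":
        d = np.sqrt(pi)
        b = (q * d[:, None]) / d[None, :]
        b = 0.5 * (b + b.T)  # enforce exact symmetry
        evals, w = np.linalg.eigh(b)
        u = w / d[:, None]
        vinv = w.T * d[None, :]
        return cls(pi=pi, evals=evals, evecs=u, inv_evecs=vinv)

    def scaled(self, rate: float) -> "EigenQ":
        """Eigensystem of ``rate * Q`` (rate-category scaling is free)."""
        return EigenQ(pi=self.pi, evals=self.evals * rate,
                      evecs=self.evecs, inv_evecs=self.inv_evecs)

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        p = (self.evecs * np.exp(self.evals * t)) @ self.inv_evecs
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_batch(self, ts: np.ndarray) -> np.ndarray:
        """(n, S, S) stack of P(t) for a vector of branch lengths."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValueError("branch lengths must be non-negative")
        e = np.exp(np.multiply.outer(ts, self.evals))       # (n, S)
        p = (self.evecs[None, :, :] * e[:, None, :]) @ self.inv_evecs
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


@dataclass
class AAModel:
    """Empirical amino-acid model (JTT or WAG) + discrete Gamma rates.

    Parameters
    ----------
    name : "JTT" or "WAG"
    alpha : Gamma shape for among-site rate variation
    k : number of discrete rate categories (equal weights 1/k)
    frequencies : "model" (published) or "empirical" (+F, from alignment)
    """

    name: str = "JTT"
    alpha: float = 1.0
    k: int = 4
    frequencies: str = "model"
    pi: Optional[np.ndarray] = None
    _eigen: Optional[EigenQ] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.name not in ("JTT", "WAG", "POISSON"):
            raise ValueError(f"unknown amino-acid model {self.name!r}")
        if not (0 < self.alpha):
            raise ValueError("gamma shape alpha must be positive")
        if self.pi is None:
            if self.name == "POISSON":
                self.pi = np.full(20, 1.0 / 20.0)
            else:
                self.pi = np.array(getattr(_aa_data, f"{self.name}_FREQS"))
        self.pi = np.asarray(self.pi, dtype=float)
        self.pi = self.pi / self.pi.sum()

    @property
    def n_states(self) -> int:
        return 20

    @property
    def n_free_parameters(self) -> int:
        # alpha is the only free rate parameter for a fixed empirical model;
        # +F adds 19 frequency parameters
        return 1 + (19 if self.frequencies == "empirical" else 0)

    def with_empirical_frequencies(self, alignment: Alignment) -> "AAModel":
        counts = np.ones(20)  # +1 pseudocount guards all-missing columns
        obs = alignment.matrix[alignment.matrix != MISSING]
        counts += np.bincount(obs, minlength=20)
        return AAModel(name=self.name, alpha=self.alpha, k=self.k,
                       frequencies="empirical", pi=counts / counts.sum())

    def q_matrix(self) -> np.ndarray:
        if self.name == "POISSON":
            exchange = np.ones(190)
        else:
            exchange = np.array(getattr(_aa_data, f"{self.name}_EXCHANGE"))
        return _build_reversible_q(exchange, self.pi)

    def eigen(self) -> EigenQ:
        if self._eigen is None:
            self._eigen = EigenQ.from_q(self.q_matrix(), self.pi)
        return self._eigen

    def rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.k)

    def transition_matrices(self, t: float) -> np.ndarray:
        """(k, 20, 20) stack of P(Q * t * r_c) over rate categories."""
        eig = self.eigen()
        return np.stack([eig.transition(t * r) for r in self.rates()])

    def replace(self, **kw) -> "AAModel":
        params = dict(name=self.name, alpha=self.alpha, k=self.k,
                      frequencies=self.frequencies, pi=self.pi)
        params.update(kw)
        if "pi" not in kw and params["name"] != self.name:
            params["pi"] = None  # switch of matrix implies its frequencies
        return AAModel(**params)


def transition_matrix(model: AAModel, t: float) -> np.ndarray:
    """Per-category transition matrices exp(Q t r_c)."""
    return model.transition_matrices(t)
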