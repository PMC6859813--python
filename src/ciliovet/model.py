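"""Reversible amino-acid substitution models with discrete-gamma rates.

A model is an exchangeability matrix plus equilibrium frequencies, scaled to
one expected substitution per unit branch length, with among-site rate
variation handled by a k-category discretised gamma (category means, mean 1)
and an optional proportion of invariant sites.

The shipped default is the Poisson model (all exchangeabilities equal),
whose transition probabilities have the F81-style closed form
P_ij(t) = pi_j + (delta_ij - pi_j) e^(-beta t); it is exact, fast, and the
synthetic-data generator simulates under the same process, so fitting is
model-matched. Empirical matrices (LG/WAG-style) can be loaded from
PAML-format .dat files via :func:`load_paml_dat`.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"  # PAML order
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
N_STATES = 20


@lru_cache(maxsize=128)
def _gamma_rates_cached(shape: float, n_categories: int) -> tuple:
    return tuple(_discrete_gamma_rates(shape, n_categories))


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of equiprobable gamma categories (mean-1 gamma)."""
    return np.array(_gamma_rates_cached(float(shape), int(n_categories)))


def _discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    if n_categories == 1:
        return np.ones(1)
    a = shape
    # boundaries of equiprobable intervals for Gamma(a, scale=1/a)
    qs = np.arange(1, n_categories) / n_categories
    bounds = gamma_dist.ppf(qs, a, scale=1.0 / a)
    edges = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X ; x in (lo, hi)] = P(a+1, a*hi) - P(a+1, a*lo) for mean-1 gamma
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(a + 1, a * edges[1:]))
    lower = gammainc(a + 1, a * edges[:-1])
    rates = n_categories * (upper - lower)
    return rates / rates.mean()


def load_paml_dat(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML .dat matrix: lower-triangular exchangeabilities + freqs."""
    vals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals.extend(float(x) for x in line.split())
    need = 190 + 20
    if len(vals) < need:
        raise ValueError(f"expected >= {need} numbers, got {len(vals)}")
    tri = vals[:190]
    freqs = np.array(vals[190:210])
    R = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            R[i, j] = R[j, i] = tri[k]
            k += 1
    return R, freqs / freqs.sum()


@dataclass
class SubstModel:
    """Scaled reversible rate matrix + Gamma(+I) rate heterogeneity."""

    name: str = "poisson"
    exchangeabilities: Optional[np.ndarray] = None  # None => all equal
    freqs: Optional[np.ndarray] = None              # None => uniform
    gamma_shape: float = 1.0
    n_categories: int = 4
    p_invariant: float = 0.0

    def __post_init__(self):
        if self.freqs is None:
            self.freqs = np.full(N_STATES, 1.0 / N_STATES)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        if not (0.0 <= self.p_invariant < 1.0):
            raise ValueError("p_invariant must be in [0, 1)")
        if self.exchangeabilities is None:
            R = np.ones((N_STATES, N_STATES))
        else:
            R = np.asarray(self.exchangeabilities, dtype=float).copy()
        np.fill_diagonal(R, 0.0)
        Q = R * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # scale: one expected substitution per unit time
        mu = -(self.freqs * np.diag(Q)).sum()
        Q /= mu
        self.Q = Q
        # symmetric eigendecomposition of D^1/2 Q D^-1/2
        d = np.sqrt(self.freqs)
        B = (Q * d[:, None]) / d[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        # P(t) = D^-1/2 U exp(wt) U^T D^1/2
        self._V = U / d[:, None]          # rows scaled by 1/sqrt(pi)
        self._W = (U * d[:, None]).T      # U^T D^1/2
        self._evals = w
        self._uniform_poisson = (
            self.exchangeabilities is None
            and self.p_invariant == 0.0
            and bool(np.allclose(self.freqs, 1.0 / N_STATES))
        )

    # -- rate categories ---------------------------------------------------
    def category_rates(self) -> np.ndarray:
        """Rates of the variable categories, rescaled for +I so that the
        overall mean rate (including the invariant class) is 1."""
        r = discrete_gamma_rates(self.gamma_shape, self.n_categories)
        if self.p_invariant > 0:
            r = r / (1.0 - self.p_invariant)
        return r

    def category_weights(self) -> np.ndarray:
        return np.full(self.n_categories, (1.0 - self.p_invariant) / self.n_categories)

    # -- transition probabilities ------------------------------------------
    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for branch length t (expected substitutions per site)."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._V * np.exp(self._evals * t)[None, :]) @ self._W
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def with_freqs(self, freqs: np.ndarray) -> "SubstModel":
        """Same model with replaced equilibrium frequencies ("+F")."""
        return SubstModel(
            name=self.name + "+F",
            exchangeabilities=self.exchangeabilities,
            freqs=freqs,
            gamma_shape=self.gamma_shape,
            n_categories=self.n_categories,
            p_invariant=self.p_invariant,
        )


def observed_freqs(rows, pseudocount: float = 1.0) -> np.ndarray:
    """Empirical amino-acid frequencies over alignment rows (gaps ignored)."""
    counts = np.full(N_STATES, pseudocount)
    for row in rows:
        for ch in row:
            i = AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def encode_alignment(rows: list[str]) -> np.ndarray:
    """Alignment rows -> int codes; gaps/unknowns -> -1 (missing)."""
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("ragged alignment")
    out = np.full((len(rows), L), -1, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            out[i, j] = AA_INDEX.get(ch, -1)
    return out
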