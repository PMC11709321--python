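"""Poisson random field sojourn densities for selected alleles.

For a mutation with scaled selection coefficient S arising at rate theta/2
per generation (theta = 4 Ne u), the expected number of segregating sites
observed with derived-allele count i in a sample of n chromosomes is

    E[xi_i] = theta * H_i(S),
    H_i(S)  = int_0^1 C(n,i) x^i (1-x)^(n-i) *
              (1 - exp(-S(1-x))) / (x (1-x) (1 - exp(-S))) dx,

with the neutral limit H_i(0) = 1/i. These weights are the forward model of
both the DFE fitter and the polymorphism simulator, which is the central
cross-module contract: the fitter fits exactly the process the generator
simulates.

The x-integral uses fixed Gauss-Legendre panels. For |S| > 30 the sojourn
density develops a boundary layer of width ~1/|S| (at x=0 for deleterious,
x=1 for beneficial alleles), so the integration domain is split there and
each panel gets its own nodes.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln

_N_NODES = 48
_SPLIT = 30.0


def _binom_coef(n: int) -> np.ndarray:
    i = np.arange(1, n)
    return np.exp(gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1))


def _ratio(x: np.ndarray, S: float) -> np.ndarray:
    """(1 - exp(-S(1-x))) / (1 - exp(-S)), numerically stable for all S."""
    if abs(S) < 1e-8:
        return 1.0 - x
    if S > 0:
        return np.expm1(-S * (1.0 - x)) / np.expm1(-S)
    # S < 0: work in logs; exp(S) < 1 so log1p(-exp(.)) is safe
    return np.exp(S * x + np.log1p(-np.exp(S * (1.0 - x))) - np.log1p(-np.exp(S)))


def sojourn_sfs_weights(S, n: int) -> np.ndarray:
    """H_i(S) for i = 1..n-1; shape (len(S), n-1).

    Computed by direct Gauss-Legendre quadrature (exact for the neutral
    polynomial integrand).
    """
    S = np.atleast_1d(np.asarray(S, dtype=float))
    nodes, weights = np.polynomial.legendre.leggauss(_N_NODES)
    coef = _binom_coef(n)
    i = np.arange(1, n)
    out = np.empty((len(S), n - 1))
    for k, s in enumerate(S):
        if s < -_SPLIT:
            c = min(0.9, _SPLIT / -s)
            panels = [(0.0, c), (c, 1.0)]
        elif s > _SPLIT:
            c = max(0.1, 1.0 - _SPLIT / s)
            panels = [(0.0, c), (c, 1.0)]
        else:
            panels = [(0.0, 1.0)]
        acc = np.zeros(n - 1)
        for lo, hi in panels:
            x = 0.5 * (hi - lo) * (nodes + 1.0) + lo
            w = 0.5 * (hi - lo) * weights
            g = _ratio(x, s) / (x * (1.0 - x))
            # integrand_i(x) = C(n,i) x^i (1-x)^(n-i) g(x)
            lx = np.log(x)
            l1x = np.log1p(-x)
            acc += coef * np.einsum(
                "x,xi->i", w * g, np.exp(i[None, :] * lx[:, None] + (n - i)[None, :] * l1x[:, None])
            )
        out[k] = acc
    return out


class SojournGrid:
    """Precomputed H_i(S) on a dense asinh-spaced grid, with interpolation.

    The grid covers S in [-1e5, 1e3]; interpolation is linear in asinh(S),
    which keeps relative error below ~5e-3 (worst in the far tails, far
    smaller near 0) at the default 1537 grid points. S=0 is a grid node, so
    the neutral limit is exact.
    """

    def __init__(self, n: int, n_points: int = 1537, s_min: float = -1e5, s_max: float = 1e3):
        self.n = n
        a_lo, a_hi = np.arcsinh(s_min), np.arcsinh(s_max)
        # symmetric accumulation around 0: build as union of two linspaces so 0 is a node
        neg = np.linspace(a_lo, 0.0, n_points // 2 + 1)
        pos = np.linspace(0.0, a_hi, n_points // 2 + 1)[1:]
        self.agrid = np.concatenate([neg, pos])
        self.sgrid = np.sinh(self.agrid)
        self.H = sojourn_sfs_weights(self.sgrid, n)

    def interp(self, S) -> np.ndarray:
        """H_i at arbitrary S, shape (len(S), n-1); clipped to grid range."""
        a = np.arcsinh(np.clip(np.asarray(S, dtype=float), self.sgrid[0], self.sgrid[-1]))
        idx = np.clip(np.searchsorted(self.agrid, a) - 1, 0, len(self.agrid) - 2)
        frac = (a - self.agrid[idx]) / (self.agrid[idx + 1] - self.agrid[idx])
        return (1.0 - frac)[:, None] * self.H[idx] + frac[:, None] * self.H[idx + 1]

    def bin_index(self, S) -> np.ndarray:
        """Nearest-node index for aggregation (used by the simulator)."""
        a = np.arcsinh(np.clip(np.asarray(S, dtype=float), self.sgrid[0], self.sgrid[-1]))
        idx = np.clip(np.searchsorted(self.agrid, a), 1, len(self.agrid) - 1)
        left = np.abs(a - self.agrid[idx - 1]) < np.abs(a - self.agrid[idx])
        return np.where(left, idx - 1, idx)


@lru_cache(maxsize=8)
def sojourn_grid(n: int) -> SojournGrid:
    return SojournGrid(n)
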