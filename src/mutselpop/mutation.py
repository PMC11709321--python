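"""4x4 nucleotide mutation models (GTR family)."""
from __future__ import annotations

import numpy as np
import scipy.linalg

from ._codes import NUCLEOTIDES, NT_INDEX


class NucleotideMutationModel:
    """A 4x4 nucleotide mutation rate matrix mu.

    Off-diagonal entries are the instantaneous mutation rates a->b
    (order A, C, G, T); diagonal entries make rows sum to zero. Equilibrium
    nucleotide frequencies may be supplied; otherwise they are solved from
    the rate matrix. Reversibility (detailed balance pi_a mu_ab = pi_b mu_ba)
    is checked on demand: the closed-form stationary distribution of the
    mutation-selection codon matrix is only valid for reversible models.
    """

    def __init__(self, rates: np.ndarray, equilibrium_freqs: np.ndarray | None = None):
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (4, 4):
            raise ValueError("mutation rate matrix must be 4x4")
        off = rates[~np.eye(4, dtype=bool)]
        if not np.all(np.isfinite(off)) or np.any(off < 0):
            raise ValueError("off-diagonal mutation rates must be finite and non-negative")
        rates = rates.copy()
        np.fill_diagonal(rates, 0.0)
        np.fill_diagonal(rates, -rates.sum(axis=1))
        self.rates = rates
        if equilibrium_freqs is None:
            equilibrium_freqs = self._solve_stationary()
        equilibrium_freqs = np.asarray(equilibrium_freqs, dtype=float)
        if equilibrium_freqs.shape != (4,) or np.any(equilibrium_freqs < 0):
            raise ValueError("equilibrium frequencies must be 4 non-negative values")
        self.equilibrium_freqs = equilibrium_freqs / equilibrium_freqs.sum()

    def _solve_stationary(self) -> np.ndarray:
        w, v = scipy.linalg.eig(self.rates, left=True, right=False)
        k = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def is_reversible(self, tol: float = 1e-8) -> bool:
        pi = self.equilibrium_freqs
        flux = pi[:, None] * self.rates
        return bool(np.allclose(flux, flux.T, atol=tol * max(1.0, np.abs(flux).max())))

    def transition_matrix(self, t: float) -> np.ndarray:
        """expm(mu * t), used for nucleotide-level polarization likelihoods."""
        return scipy.linalg.expm(self.rates * t)

    @property
    def total_rate(self) -> float:
        """Mean mutation rate per site at equilibrium (units of mu)."""
        return float(-np.dot(self.equilibrium_freqs, np.diag(self.rates)))

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(cls, rate: float = 1.0) -> "NucleotideMutationModel":
        m = np.full((4, 4), rate, dtype=float)
        return cls(m, np.full(4, 0.25))

    @classmethod
    def hky(cls, kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25)) -> "NucleotideMutationModel":
        """HKY: transitions (A<->G, C<->T) scaled by kappa, GTR-reversible."""
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        m = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                ts = {frozenset((NT_INDEX["A"], NT_INDEX["G"])), frozenset((NT_INDEX["C"], NT_INDEX["T"]))}
                rate = kappa if frozenset((a, b)) in ts else 1.0
                m[a, b] = rate * freqs[b]
        return cls(m, freqs)

    @classmethod
    def gtr(cls, exchangeabilities, freqs) -> "NucleotideMutationModel":
        """GTR from 6 exchangeabilities (AC, AG, AT, CG, CT, GT) and frequencies."""
        ex = np.asarray(exchangeabilities, dtype=float)
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        m = np.zeros((4, 4))
        for (a, b), e in zip(pairs, ex):
            m[a, b] = e * freqs[b]
            m[b, a] = e * freqs[a]
        return cls(m, freqs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NucleotideMutationModel(rates={self.rates!r})"
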