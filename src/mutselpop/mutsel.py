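"""Mutation-selection codon machinery.

The model: each codon site i carries a vector F of 20 scaled amino-acid
log-fitnesses (dimensionless, in units of 4Ne). The substitution rate from
sense codon a to sense codon b at that site is

    q_ab = 0                                   if a,b differ at >1 position,
    q_ab = mu_ab                               if synonymous,
    q_ab = mu_ab * dF / (1 - exp(-dF))         otherwise, dF = F_b - F_a,

i.e. the underlying nucleotide mutation rate times the scaled fixation
probability of a mutation with scaled selection coefficient S0 = dF. The
scaled selection coefficient of any single-nucleotide change classifies it
as deleterious (D0: S0 < -1), nearly-neutral (N0: -1 <= S0 <= 1) or
beneficial non-adaptive (B0: S0 > 1); synonymous changes are SYN with S0=0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._codes import (
    CODON_AA,
    CODON_NT,
    N_CODONS,
    NEI_AA_TO,
    NEI_FROM_NT,
    NEI_IS_STOP,
    NEI_IS_SYN,
    NEI_TARGET,
    NEI_TO_NT,
    SENSE_CODONS,
    codons_differ_at,
)
from .mutation import NucleotideMutationModel

CLASS_DELETERIOUS = "D0"
CLASS_NEUTRAL = "N0"
CLASS_BENEFICIAL = "B0"
CLASS_SYNONYMOUS = "SYN"
SELECTION_CLASSES = (CLASS_DELETERIOUS, CLASS_NEUTRAL, CLASS_BENEFICIAL)

_DF_LIMIT = 1e-8


def fixation_factor(S):
    """Scaled fixation probability omega(S) = S / (1 - exp(-S)), omega(0)=1.

    Works elementwise on arrays; the |S| < 1e-8 branch routes to the limit to
    avoid 0/0. Stable for strongly negative S (returns ~ -S * exp(S) -> 0)
    and strongly positive S (returns ~ S).
    """
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    small = np.abs(S) < _DF_LIMIT
    out[small] = 1.0
    s = S[~small]
    with np.errstate(over="ignore"):
        out[~small] = s / -np.expm1(-s)
    return out if out.ndim else float(out)


@dataclass
class SiteFitnessProfile:
    """20 scaled amino-acid log-fitnesses at one alignment site.

    The gauge is mean-zero over the 20 amino acids (fitnesses are only
    identified up to an additive constant).
    """

    site: int
    F: np.ndarray
    converged: bool = True
    uninformative: bool = False

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (20,):
            raise ValueError("profile must hold 20 fitness values")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fitness values must be finite")
        self.F = self.F - self.F.mean()

    @classmethod
    def _from_validated(cls, site: int, F: np.ndarray) -> "SiteFitnessProfile":
        """Construct from a row already known finite and mean-centered.

        Per-profile validation dominates landscape sampling at exome scale;
        bulk generators that center whole matrices use this fast path.
        """
        self = object.__new__(cls)
        self.site = site
        self.F = F
        self.converged = True
        self.uninformative = False
        return self


def profiles_to_matrix(profiles) -> np.ndarray:
    """Stack profiles into an (n_sites, 20) fitness matrix."""
    return np.stack([p.F for p in profiles])


@dataclass
class CodonRateMatrix:
    """61x61 mutation-selection generator for one site."""

    q: np.ndarray
    mu: NucleotideMutationModel
    profile: SiteFitnessProfile

    @property
    def stationary(self) -> np.ndarray:
        return stationary_distribution(self)


def build_site_rate_matrix(mu: NucleotideMutationModel, profile: SiteFitnessProfile) -> CodonRateMatrix:
    """Mutation-selection generator for one site (61x61).

    Synonymous single-step entries equal the underlying nucleotide rate;
    non-synonymous entries are scaled by the fixation factor of dF; multi-step
    entries are zero; rows sum to zero.
    """
    F = profile.F
    q = np.zeros((N_CODONS, N_CODONS))
    aa = CODON_AA
    mu_nt = mu.rates
    targets = NEI_TARGET
    valid = targets >= 0
    rows, cols = np.nonzero(valid)
    t = targets[rows, cols]
    dF = F[aa[t]] - F[aa[rows]]
    rate = mu_nt[NEI_FROM_NT[rows, cols], NEI_TO_NT[rows, cols]] * fixation_factor(dF)
    q[rows, t] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return CodonRateMatrix(q=q, mu=mu, profile=profile)


def codon_psi(mu: NucleotideMutationModel) -> np.ndarray:
    """Product of equilibrium nucleotide frequencies over codon positions."""
    f = mu.equilibrium_freqs
    return f[CODON_NT[:, 0]] * f[CODON_NT[:, 1]] * f[CODON_NT[:, 2]]


def stationary_distribution(matrix: CodonRateMatrix) -> np.ndarray:
    """Stationary codon distribution of a mutation-selection matrix.

    For a reversible mutation model the closed form pi_c ~ psi_c * exp(F_aa(c))
    applies (psi_c: product of equilibrium nucleotide frequencies of the
    codon). Non-reversible models fall back to a numerical null-space solve
    with a warning.
    """
    if matrix.mu.is_reversible():
        return stationary_from_profile(matrix.mu, matrix.profile.F)
    warnings.warn("non-reversible mutation model: solving stationary distribution numerically")
    q = matrix.q
    w, v = scipy.linalg.eig(q, left=True, right=False)
    k = int(np.argmin(np.abs(w)))
    pi = np.abs(np.real(v[:, k]))
    return pi / pi.sum()


def stationary_from_profile(mu: NucleotideMutationModel, F: np.ndarray) -> np.ndarray:
    """Closed-form pi_c ~ psi_c exp(F_aa(c)) for a single site."""
    logpi = np.log(codon_psi(mu)) + np.asarray(F, dtype=float)[CODON_AA]
    logpi -= logpi.max()
    pi = np.exp(logpi)
    return pi / pi.sum()


def stationary_matrix(mu: NucleotideMutationModel, Fmat: np.ndarray) -> np.ndarray:
    """(n_sites, 61) stationary distributions for a matrix of profiles."""
    logpsi = np.log(codon_psi(mu))
    logpi = logpsi[None, :] + Fmat[:, CODON_AA]
    logpi -= logpi.max(axis=1, keepdims=True)
    pi = np.exp(logpi)
    return pi / pi.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ScaledSelection:
    """Scaled selection coefficient S0 = 4Ne*s of one codon change and its class."""

    S0: float
    selection_class: str


def classify_S0(S0) -> np.ndarray:
    """Vectorized D0/N0/B0 assignment; boundaries (S0 = +-1) go to N0."""
    S0 = np.asarray(S0, dtype=float)
    out = np.full(S0.shape, CLASS_NEUTRAL, dtype=object)
    out[S0 < -1.0] = CLASS_DELETERIOUS
    out[S0 > 1.0] = CLASS_BENEFICIAL
    return out


def scaled_selection(profile: SiteFitnessProfile, codon_from: str, codon_to: str) -> ScaledSelection:
    """S0 of a single-nucleotide codon change under a site profile."""
    from ._codes import CODON_INDEX

    a = CODON_INDEX.get(codon_from.upper())
    b = CODON_INDEX.get(codon_to.upper())
    if a is None or b is None:
        raise ValueError(f"not a sense codon: {codon_from!r} or {codon_to!r}")
    if len(codons_differ_at(a, b)) > 1:
        raise ValueError(f"codons {codon_from}->{codon_to} differ at more than one position")
    if CODON_AA[a] == CODON_AA[b]:
        return ScaledSelection(0.0, CLASS_SYNONYMOUS)
    S0 = float(profile.F[CODON_AA[b]] - profile.F[CODON_AA[a]])
    return ScaledSelection(S0, str(classify_S0(S0)))


# -- vectorized per-exome change tables -----------------------------------

def change_tables(codons: np.ndarray, Fmat: np.ndarray, mu: NucleotideMutationModel):
    """Per-site tables of the 9 single-nucleotide changes of each codon.

    Parameters
    ----------
    codons : (L,) sense-codon indices of the (ancestral) exome
    Fmat : (L, 20) site fitness matrix
    mu : nucleotide mutation model

    Returns a dict of (L, 9) arrays: ``target`` (codon index, -1 for stop),
    ``mu_weight`` (nucleotide mutation rate; 0 for stop-gaining changes),
    ``is_syn``, ``dF`` (S0; 0 for synonymous/stop), ``rate`` (mutation rate
    times fixation factor: the substitution flux of the change).
    """
    codons = np.asarray(codons)
    target = NEI_TARGET[codons]
    is_stop = NEI_IS_STOP[codons]
    is_syn = NEI_IS_SYN[codons]
    muw = mu.rates[NEI_FROM_NT[codons], NEI_TO_NT[codons]].copy()
    muw[is_stop] = 0.0
    aa_from = CODON_AA[codons]
    aa_to = NEI_AA_TO[codons]
    rows = np.arange(len(codons))[:, None]
    dF = np.where(
        is_stop | is_syn,
        0.0,
        Fmat[rows, np.where(aa_to < 0, 0, aa_to)] - Fmat[rows, aa_from[:, None]],
    )
    rate = muw * np.where(is_syn, 1.0, fixation_factor(dF))
    rate[is_stop] = 0.0
    return {
        "target": target,
        "mu_weight": muw,
        "is_stop": is_stop,
        "is_syn": is_syn,
        "dF": dF,
        "rate": rate,
    }
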