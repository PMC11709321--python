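"""Distribution-of-fitness-effects inference from site-frequency spectra.

The parametric DFE is a mixture over the population-scaled selection
coefficient S: with probability 1-p_b, -S follows a Gamma distribution with
mean -beta_d (beta_d <= -1) and shape b (b >= 0.2); with probability p_b, S
follows an exponential with mean beta_b (beta_b >= 1). A discretized
alternative puts free masses on fixed S bins whose edges straddle the
selection-class thresholds at -1 and +1.

Fitting maximizes an independent-Poisson likelihood over SFS frequency bins
(optionally plus a divergence count), with the mutation-rate scale theta
profiled analytically and an optional mispolarization nuisance epsilon that
mixes each bin with its frequency-mirrored counterpart.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize
import scipy.stats
from scipy.special import gammaincc, gammainc, expit
from scipy.stats import qmc

from .mutsel import fixation_factor
from .prf import sojourn_grid, sojourn_sfs_weights

_GAMMA_NODES = 128
_EXP_NODES = 64


def _unit_gauss(n):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@dataclass
class DFEModel:
    """Gamma (S<=0) + exponential (S>0) mixture, with mispolarization nuisance."""

    beta_d: float  # mean of the deleterious component, <= -1
    b: float       # Gamma shape, >= 0.2
    p_b: float     # probability that S > 0
    beta_b: float  # mean of the beneficial exponential, >= 1
    epsilon: float = 0.0  # mispolarization probability, in [0, 0.5]

    def __post_init__(self):
        if not (self.beta_d <= -1.0):
            raise ValueError("beta_d must be <= -1")
        if not (self.b >= 0.2):
            raise ValueError("b must be >= 0.2")
        if not (0.0 <= self.p_b <= 1.0):
            raise ValueError("p_b must be in [0, 1]")
        if not (self.beta_b >= 1.0):
            raise ValueError("beta_b must be >= 1")
        if not (0.0 <= self.epsilon <= 0.5):
            raise ValueError("epsilon must be in [0, 0.5]")

    def quadrature(self):
        """(S nodes, probability weights) for integrals against the density."""
        u, w = _unit_gauss(_GAMMA_NODES)
        m = -self.beta_d
        t = scipy.stats.gamma.ppf(u, self.b, scale=m / self.b)
        S_neg, w_neg = -t, (1.0 - self.p_b) * w
        u2, w2 = _unit_gauss(_EXP_NODES)
        S_pos = -self.beta_b * np.log1p(-u2)
        w_pos = self.p_b * w2
        return np.concatenate([S_neg, S_pos]), np.concatenate([w_neg, w_pos])


@dataclass
class PointMassDFE:
    """Degenerate DFE concentrated at a single S (mostly a test/oracle device)."""

    S: float
    epsilon: float = 0.0

    def quadrature(self):
        return np.array([self.S]), np.array([1.0])


_DEFAULT_EDGES = (-np.inf, -100.0, -10.0, -1.0, 0.0, 1.0, 10.0, np.inf)


@dataclass
class DiscreteDFE:
    """Non-parametric DFE: masses on fixed S bins.

    Default bin edges (-inf,-100,-10,-1,0,1,10,inf) straddle the class
    thresholds at -1 and +1 so class probabilities are plain mass sums.
    Within a bin, mass spreads uniformly in asinh(S) between the bin's
    representative nodes (a modeling choice, documented; the open-ended bins
    use 100..10000 and 10..1000).
    """

    masses: np.ndarray
    edges: tuple = _DEFAULT_EDGES
    epsilon: float = 0.0
    nodes_per_bin: int = 8

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.masses) != len(self.edges) - 1:
            raise ValueError("need one mass per bin")
        if np.any(self.masses < -1e-12) or not np.isclose(self.masses.sum(), 1.0):
            raise ValueError("masses must be non-negative and sum to 1")

    def _bin_nodes(self, k):
        lo, hi = self.edges[k], self.edges[k + 1]
        if np.isinf(lo):
            lo = -100.0 * abs(hi if hi != 0 else 1.0)
        if np.isinf(hi):
            hi = 100.0 * abs(lo if lo != 0 else 1.0)
        a = np.linspace(np.arcsinh(lo), np.arcsinh(hi), self.nodes_per_bin + 2)[1:-1]
        return np.sinh(a)

    def quadrature(self):
        S, w = [], []
        for k, m in enumerate(self.masses):
            nodes = self._bin_nodes(k)
            S.append(nodes)
            w.append(np.full(len(nodes), m / len(nodes)))
        return np.concatenate(S), np.concatenate(w)


def dfe_density(model: DFEModel, S) -> np.ndarray:
    """Mixture density of the parametric DFE at S (elementwise)."""
    S = np.asarray(S, dtype=float)
    m = -model.beta_d
    neg = (1.0 - model.p_b) * scipy.stats.gamma.pdf(-S, model.b, scale=m / model.b)
    pos = model.p_b * scipy.stats.expon.pdf(S, scale=model.beta_b)
    return np.where(S <= 0, neg, np.where(S > 0, pos, 0.0))


@dataclass
class ClassPosterior:
    """P[D|x], P[N|x], P[B|x]: population-scale class probabilities."""

    p_del: float
    p_neutral: float
    p_ben: float

    def as_array(self):
        return np.array([self.p_del, self.p_neutral, self.p_ben])


def class_probabilities(model) -> ClassPosterior:
    """P[S<-1], P[-1<S<1], P[S>1] under a fitted DFE.

    Closed forms for the parametric mixture: P[B] = p_b exp(-1/beta_b) and
    P[D] = (1-p_b) Q(b, b/(-beta_d)) via the regularized incomplete Gamma.
    """
    if isinstance(model, DFEModel):
        m = -model.beta_d
        p_d = (1.0 - model.p_b) * float(gammaincc(model.b, model.b / m))
        p_bb = model.p_b * float(np.exp(-1.0 / model.beta_b))
        return ClassPosterior(p_d, 1.0 - p_d - p_bb, p_bb)
    if isinstance(model, DiscreteDFE):
        edges = np.asarray(model.edges)
        p_d = float(model.masses[edges[1:] <= -1.0].sum())
        p_bb = float(model.masses[edges[:-1] >= 1.0].sum())
        return ClassPosterior(p_d, 1.0 - p_d - p_bb, p_bb)
    if isinstance(model, PointMassDFE):
        p_d = 1.0 if model.S < -1 else 0.0
        p_bb = 1.0 if model.S > 1 else 0.0
        return ClassPosterior(p_d, 1.0 - p_d - p_bb, p_bb)
    raise TypeError(f"unknown DFE model type {type(model)!r}")


def _mix_mirror(E: np.ndarray, epsilon: float) -> np.ndarray:
    if epsilon == 0.0:
        return E
    return (1.0 - epsilon) * E + epsilon * E[::-1]


def expected_sfs(model, theta: float, n: int, L: float, use_grid: bool = False) -> np.ndarray:
    """Expected SFS counts E_1..E_{n-1} under a DFE model.

    E_i = L * theta * int phi(S) H_i(S) dS, with the mispolarization mixing
    E'_i = (1-eps) E_i + eps E_{n-i}. ``use_grid`` interpolates H from the
    cached dense grid (the fitter's fast path) instead of direct quadrature.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if theta < 0 or L <= 0:
        raise ValueError("theta must be >= 0 and L > 0")
    S, w = model.quadrature()
    H = sojourn_grid(n).interp(S) if use_grid else sojourn_sfs_weights(S, n)
    E = L * theta * (w @ H)
    if not np.all(np.isfinite(E)):
        raise FloatingPointError("expected SFS quadrature did not converge")
    return _mix_mirror(E, getattr(model, "epsilon", 0.0))


def expected_divergence(model, d_neutral: float, L: float) -> float:
    """Expected substitution count E[D] = L d_neutral int phi(S) omega(S) dS."""
    if d_neutral < 0:
        raise ValueError("d_neutral must be >= 0")
    S, w = model.quadrature()
    val = float(L * d_neutral * np.dot(w, fixation_factor(S)))
    if not np.isfinite(val):
        raise FloatingPointError("divergence quadrature did not converge")
    return val


# -- fitting ---------------------------------------------------------------

@dataclass
class DFEFitResult:
    model: object
    loglik: float
    theta: float
    converged: bool
    degenerate: bool = False
    starts: list = field(default_factory=list)

    @property
    def class_posterior(self) -> ClassPosterior:
        return class_probabilities(self.model)


def _poisson_ll(counts, means):
    means = np.maximum(means, 1e-300)
    return float(np.sum(counts * np.log(means) - means))


def _sfs_arrays(sfs):
    """Accept a SiteFrequencySpectrum or an (xi, n, L) tuple."""
    if hasattr(sfs, "counts"):
        return np.asarray(sfs.counts, dtype=float), int(sfs.n), float(sfs.L)
    xi, n, L = sfs
    return np.asarray(xi, dtype=float), int(n), float(L)


def fit_dfe(
    sfs_x,
    sfs_syn,
    divergence=None,
    form: str = "parametric",
    fit_epsilon: bool = False,
    n_starts: int = 8,
    seed: int = 0,
) -> DFEFitResult:
    """Maximum-likelihood DFE fit to a selected SFS with a neutral anchor.

    Parameters
    ----------
    sfs_x, sfs_syn :
        Selected-class and synonymous spectra (objects with counts/n/L, or
        (xi, n, L) tuples) at matching sample size n.
    divergence :
        Optional ((D_x, L_x), (D_syn, L_syn)) substitution counts and
        opportunities; adds a Poisson divergence bin with expectation
        L_x * (D_syn/L_syn) * int phi(S) omega(S) dS.
    form :
        "parametric" (Gamma+exponential mixture) or "discrete" (binned masses).

    theta is profiled analytically (Poisson MLE given the spectrum shapes);
    multi-start bounded quasi-Newton from a seeded quasi-random sequence.
    """
    xi_x, n, L_x = _sfs_arrays(sfs_x)
    xi_syn, n_syn, L_syn = _sfs_arrays(sfs_syn)
    if n != n_syn:
        raise ValueError("selected and synonymous SFS must share sample size n")
    if xi_syn.sum() <= 0:
        raise ValueError("synonymous SFS is empty: no neutral anchor for theta")
    grid = sojourn_grid(n)
    i = np.arange(1, n)
    m_syn_base = L_syn / i

    d_neutral = None
    if divergence is not None:
        (D_x, L_x_div), (D_syn, L_syn_div) = divergence
        if L_syn_div <= 0:
            raise ValueError("synonymous divergence opportunity must be > 0")
        d_neutral = D_syn / L_syn_div

    degenerate = xi_x.sum() == 0

    if form == "parametric":
        builder, bounds, start_box = _parametric_space(fit_epsilon, degenerate)
    elif form == "discrete":
        builder, bounds, start_box = _discrete_space(fit_epsilon)
    else:
        raise ValueError("form must be 'parametric' or 'discrete'")

    def negll(theta_vec):
        model = builder(theta_vec)
        S, w = model.quadrature()
        shape_x = w @ grid.interp(S)
        eps = getattr(model, "epsilon", 0.0)
        m_x = _mix_mirror(L_x * shape_x, eps)
        m_syn = _mix_mirror(m_syn_base, eps)
        m_all = np.concatenate([m_syn, m_x])
        x_all = np.concatenate([xi_syn, xi_x])
        denom = m_all.sum()
        if not np.isfinite(denom) or denom <= 0:
            return 1e12
        th = x_all.sum() / denom
        ll = _poisson_ll(x_all, th * m_all)
        if d_neutral is not None:
            lam = L_x_div * d_neutral * float(np.dot(w, fixation_factor(S)))
            ll += D_x * np.log(max(lam, 1e-300)) - lam
        return -ll if np.isfinite(ll) else 1e12

    sob = qmc.Sobol(d=len(bounds), scramble=True, seed=seed)
    pts = sob.random(max(1, n_starts))
    lo = np.array([b[0] for b in start_box])
    hi = np.array([b[1] for b in start_box])
    starts = lo + pts * (hi - lo)

    best, log = None, []
    for p0 in starts:
        res = scipy.optimize.minimize(
            negll, p0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        log.append({"x0": p0.tolist(), "fun": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res

    model = builder(best.x)
    # recompute profiled theta at the optimum
    S, w = model.quadrature()
    eps = getattr(model, "epsilon", 0.0)
    m_all = np.concatenate(
        [_mix_mirror(m_syn_base, eps), _mix_mirror(L_x * (w @ grid.interp(S)), eps)]
    )
    theta_hat = float(np.concatenate([xi_syn, xi_x]).sum() / m_all.sum())
    return DFEFitResult(
        model=model,
        loglik=-float(best.fun),
        theta=theta_hat,
        converged=bool(best.success),
        degenerate=degenerate,
        starts=log,
    )


def _parametric_space(fit_epsilon: bool, degenerate: bool):
    """Transformed parameter space: [log(-beta_d), log b, logit p_b, log beta_b (, eps)]."""

    def builder(v):
        p_b = 0.0 if degenerate else float(expit(v[2]))
        eps = float(v[4]) if fit_epsilon else 0.0
        return DFEModel(
            beta_d=-float(np.exp(v[0])),
            b=float(np.exp(v[1])),
            p_b=p_b,
            beta_b=float(np.exp(v[3])),
            epsilon=eps,
        )

    bounds = [
        (0.0, np.log(1e5)),
        (np.log(0.2), np.log(20.0)),
        (-15.0, 7.0),
        (0.0, np.log(200.0)),
    ]
    start_box = [(np.log(2.0), np.log(2e3)), (np.log(0.25), np.log(2.0)), (-6.0, 0.0), (0.1, np.log(20.0))]
    if fit_epsilon:
        bounds.append((0.0, 0.5))
        start_box.append((0.0, 0.2))
    return builder, bounds, start_box


def _discrete_space(fit_epsilon: bool):
    n_bins = len(_DEFAULT_EDGES) - 1

    def builder(v):
        z = np.concatenate([v[: n_bins - 1], [0.0]])
        z = z - z.max()
        masses = np.exp(z)
        masses /= masses.sum()
        eps = float(v[n_bins - 1]) if fit_epsilon else 0.0
        return DiscreteDFE(masses=masses, epsilon=eps)

    bounds = [(-20.0, 20.0)] * (n_bins - 1)
    start_box = [(-3.0, 3.0)] * (n_bins - 1)
    if fit_epsilon:
        bounds.append((0.0, 0.5))
        start_box.append((0.0, 0.2))
    return builder, bounds, start_box
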