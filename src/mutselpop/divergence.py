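"""Terminal-branch divergence: ancestral reconstruction, substitution
mapping, class-conditional dN/dS and the inflation statistic delta(dN/dS).

A substitution on the terminal branch is a fixed difference between the
codon at the base of the branch (reconstructed from outgroups) and the
ancestral state of the extant population, at a site not segregating in the
population. Each single-nucleotide substitution is classified SYN or by the
selection class of its scaled coefficient S0 computed on the base-of-branch
codon as source (direction matters). Multi-nucleotide codon differences are
excluded from both counts and opportunity, because decomposing them into
ordered single steps is ambiguous; the excluded sites are reported so the
opportunity table can be recomputed without them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._codes import CODON_AA, N_CODONS, codons_differ_at
from .mutation import NucleotideMutationModel
from .mutsel import (
    CLASS_SYNONYMOUS,
    SELECTION_CLASSES,
    classify_S0,
    fixation_factor,
)
from .phylo import CodonAlignment, Phylogeny, _Propagator, neutral_codon_matrix
from .popgen import AncestralExome, OpportunityTable

__all__ = [
    "DivergenceTable",
    "SubstitutionCounts",
    "reconstruct_branch_base",
    "map_substitutions",
    "dnds_by_class",
    "delta_dnds",
    "omega_of_S",
    "invert_omega",
]


# -- omega(S) and its inverse ----------------------------------------------

def omega_of_S(S):
    """Relative fixation rate omega(S) = S / (1 - e^{-S}), omega(0) = 1."""
    return fixation_factor(S)


def invert_omega(omega: float, s_lo: float = -500.0, s_hi: float = 500.0) -> float:
    """Solve omega(S) = omega for S by bracketed root finding (xtol 1e-10).

    omega is strictly increasing with range (0, inf), so any positive omega
    has a unique preimage.
    """
    omega = float(omega)
    if omega <= 0:
        raise ValueError("omega must be positive")
    if omega == 1.0:
        return 0.0
    f = lambda s: float(fixation_factor(s)) - omega
    lo, hi = (0.0, 1.0) if omega > 1 else (-1.0, 0.0)
    while f(hi) < 0:
        hi *= 2.0
        if hi > s_hi:
            raise ValueError(f"omega={omega} out of invertible range (S > {s_hi})")
    while f(lo) > 0:
        lo *= 2.0
        if lo < s_lo:
            raise ValueError(f"omega={omega} out of invertible range (S < {s_lo})")
    return float(brentq(f, lo, hi, xtol=1e-10))


# -- ancestral reconstruction ----------------------------------------------

def _parent_array(tree: Phylogeny) -> np.ndarray:
    parent = np.full(tree.n_nodes, -1, dtype=np.int64)
    for k in range(tree.n_nodes):
        for c in tree.children[k]:
            parent[c] = k
    return parent


def reconstruct_branch_base(
    alignment: CodonAlignment,
    tree: Phylogeny,
    mu: NucleotideMutationModel,
    focal_label: str = "focal",
    chunk: int = 2000,
) -> AncestralExome:
    """Joint-ML codon at the base of the focal terminal branch, per site.

    Max-product (Viterbi-style) message passing under the neutral codon
    model gives the jointly most likely ancestral states; the state at the
    focal leaf's parent is read off by backtracking from the root. The
    reported probability is the sum-product marginal posterior of that codon
    at that node, a per-site reconstruction confidence.

    Rate variation across sites is not modeled; the neutral, site-homogeneous
    model is adequate at the shallow divergences this is used for.
    """
    missing = [lab for lab in tree.leaf_labels if lab not in alignment.taxa]
    if missing:
        raise ValueError(f"alignment is missing taxa required by the tree: {missing}")
    if focal_label not in tree.leaf_ids:
        raise ValueError(f"tree has no leaf named {focal_label!r}")
    matrix = neutral_codon_matrix(mu)
    pi = matrix.stationary
    prop = _Propagator(matrix.q, pi)
    parent = _parent_array(tree)
    target = parent[tree.leaf_ids[focal_label]]
    # path from root down to the target node
    path = [target]
    while parent[path[-1]] != -1:
        path.append(parent[path[-1]])
    path = path[::-1]  # root .. target

    # transition matrix P_ab(t) = P[a -> b in time t] per node's parent edge
    P = {c: prop.apply(tree.edge_length[c], np.eye(N_CODONS)).T for c in range(tree.n_nodes) if parent[c] != -1}
    logP = {c: np.log(np.maximum(p, 1e-300)) for c, p in P.items()}
    logpi = np.log(np.maximum(pi, 1e-300))

    row = {tax: t for t, tax in enumerate(alignment.taxa)}
    # the model is site-homogeneous, so the reconstruction depends only on
    # the column pattern: solve each distinct pattern once
    columns = np.stack([alignment.codons[row[lab]] for lab in tree.leaf_labels], axis=1)
    patterns, inverse = np.unique(columns, axis=0, return_inverse=True)
    leaf_state = {
        tree.leaf_ids[lab]: patterns[:, t] for t, lab in enumerate(tree.leaf_labels)
    }
    n_pat = len(patterns)
    codons = np.empty(n_pat, dtype=np.int64)
    probs = np.empty(n_pat)
    for start in range(0, n_pat, chunk):
        sl = slice(start, min(start + chunk, n_pat))
        c_chunk, p_chunk = _reconstruct_chunk(tree, parent, path, logP, P, logpi, pi, leaf_state, sl)
        codons[sl] = c_chunk
        probs[sl] = p_chunk
    return AncestralExome(codons=codons[inverse], polarization_prob=probs[inverse])


def _reconstruct_chunk(tree, parent, path, logP, P, logpi, pi, leaf_state, sl):
    S = sl.stop - sl.start
    # upward pass: per node, log evidence u[k][s, a] of the subtree below k
    # given state a at k; max-product messages with argmax for backtracking.
    logu = {}
    msg_arg = {}  # child -> (S, 61) argmax of the child state given parent state
    logm = {}  # child -> (S, 61) max-product message to parent
    sum_logm = {}  # child -> (S, 61) sum-product message (for the marginal)
    for k in range(tree.n_nodes):
        is_leaf = not tree.children[k]
        if is_leaf:
            s = leaf_state[k][sl]
            u = np.zeros((S, N_CODONS))
            obs = s >= 0
            u[obs] = -np.inf
            u[np.nonzero(obs)[0], s[obs]] = 0.0
            logu[k] = u
        else:
            logu[k] = sum(logm[c] for c in tree.children[k])
        if parent[k] != -1:
            if is_leaf and bool(np.all(s >= 0)):
                # observed leaf: the max/sum over b collapses to b = state
                logm[k] = logP[k][:, s].T
                msg_arg[k] = np.broadcast_to(s[:, None], (S, N_CODONS))
                sum_logm[k] = logm[k]
                continue
            # score[s, a, b] = logP[k][a, b] + logu[k][s, b]
            score = logP[k][None, :, :] + logu[k][:, None, :]
            msg_arg[k] = score.argmax(axis=2)
            logm[k] = np.take_along_axis(score, msg_arg[k][:, :, None], axis=2)[:, :, 0]
            with np.errstate(divide="ignore"):
                sum_logm[k] = _logmatvec(logP[k], logu[k])

    # backtrack from the root down the path to the target node
    state = (logpi[None, :] + logu[tree.root]).argmax(axis=1)
    for node in path[1:]:
        state = msg_arg[node][np.arange(S), state]

    # sum-product marginal posterior at the target node
    target = path[-1]
    log_out = np.broadcast_to(logpi, (S, N_CODONS)).copy()
    for node, nxt in zip(path[:-1], path[1:]):
        for c in tree.children[node]:
            if c != nxt:
                log_out = log_out + sum_logm[c]
        # propagate outside message through the edge into nxt
        log_out = _logmatvec(logP[nxt].T, log_out)
    log_post = log_out + logu[target]
    mx = log_post.max(axis=1, keepdims=True)
    w = np.exp(log_post - mx)
    post = w / w.sum(axis=1, keepdims=True)
    return state, post[np.arange(S), state]


def _logmatvec(logA: np.ndarray, logv: np.ndarray) -> np.ndarray:
    """log(A @ exp(logv_s)) per site row, stably: out[s, a] = LSE_b(logA[a,b] + logv[s,b])."""
    mx = logv.max(axis=1, keepdims=True)
    finite = np.isfinite(mx[:, 0])
    out = np.full_like(logv, -np.inf)
    if finite.any():
        v = np.exp(logv[finite] - mx[finite])
        prod = v @ np.exp(logA).T
        out[finite] = np.log(np.maximum(prod, 1e-300)) + mx[finite]
    return out


# -- substitution mapping --------------------------------------------------

@dataclass
class SubstitutionCounts:
    """Per-class substitution counts on the terminal branch.

    ``excluded_multi_step`` lists sites whose codon difference spans more
    than one nucleotide (dropped from counts; recompute opportunities with
    these sites excluded). ``skipped_segregating`` lists compared sites that
    were skipped because they segregate in the population.
    """

    counts: dict
    excluded_multi_step: np.ndarray
    skipped_segregating: np.ndarray
    records: pd.DataFrame

    @property
    def D_syn(self) -> float:
        return self.counts[CLASS_SYNONYMOUS]

    def D(self, x: str) -> float:
        return self.counts[x]


def map_substitutions(
    base_exome: AncestralExome,
    population_exome: AncestralExome,
    Fmat: np.ndarray,
    segregating_sites=(),
) -> SubstitutionCounts:
    """Classify fixed differences between branch base and population ancestor.

    Sites segregating in the population are skipped (only fixed differences
    count as substitutions). The base-of-branch codon is the source when
    computing S0 = F(derived aa) - F(ancestral aa), so direction matters.
    """
    base = np.asarray(base_exome.codons, dtype=np.int64)
    pop = np.asarray(population_exome.codons, dtype=np.int64)
    if base.shape != pop.shape:
        raise ValueError("exomes are not aligned site-for-site")
    Fmat = np.asarray(Fmat, dtype=float)
    if Fmat.shape != (len(base), 20):
        raise ValueError("fitness matrix must be (n_sites, 20)")
    seg = np.zeros(len(base), dtype=bool)
    seg_idx = np.asarray(list(segregating_sites), dtype=np.int64)
    if seg_idx.size:
        seg[seg_idx] = True

    diff = np.nonzero(base != pop)[0]
    counts = {CLASS_SYNONYMOUS: 0, **{x: 0 for x in SELECTION_CLASSES}}
    multi, skipped, rows = [], [], []
    for site in diff:
        if seg[site]:
            skipped.append(site)
            continue
        a, b = int(base[site]), int(pop[site])
        if len(codons_differ_at(a, b)) > 1:
            multi.append(site)
            continue
        aa_a, aa_b = int(CODON_AA[a]), int(CODON_AA[b])
        if aa_a == aa_b:
            cls, s0 = CLASS_SYNONYMOUS, 0.0
        else:
            s0 = float(Fmat[site, aa_b] - Fmat[site, aa_a])
            cls = str(classify_S0([s0])[0])
        counts[cls] += 1
        rows.append((int(site), a, b, s0, cls))
    records = pd.DataFrame(rows, columns=["site", "from_codon", "to_codon", "S0", "selection_class"])
    return SubstitutionCounts(
        counts=counts,
        excluded_multi_step=np.asarray(multi, dtype=np.int64),
        skipped_segregating=np.asarray(skipped, dtype=np.int64),
        records=records,
    )


# -- class-conditional rates -----------------------------------------------

@dataclass
class DivergenceTable:
    """Per-class substitution counts, opportunities and rates.

    dN(x) = D(x)/L(x), dS = D_syn/L_syn. The inflation statistic delta is
    (dN - dN(S0<1)) / dN on the pooled non-synonymous rate, where dN(S0<1)
    removes the B0 substitutions but keeps the full non-synonymous
    opportunity; it reduces to D(B0) / D_nonsyn.
    """

    D: dict
    D_syn: float
    L: dict
    L_syn: float
    dN: dict = field(default_factory=dict)
    dS: float = 0.0
    dnds: dict = field(default_factory=dict)
    dS_defined: bool = True
    delta: float | None = None

    def __post_init__(self):
        if self.D_syn < 0 or any(v < 0 for v in self.D.values()):
            raise ValueError("substitution counts must be >= 0")
        if self.L_syn <= 0 or any(v <= 0 for v in self.L.values()):
            raise ValueError("opportunities must be > 0")
        if not self.dN:
            self.dN = {x: self.D[x] / self.L[x] for x in SELECTION_CLASSES}
        self.dS = self.D_syn / self.L_syn
        self.dS_defined = self.D_syn > 0
        if self.dS_defined:
            self.dnds = {x: self.dN[x] / self.dS for x in SELECTION_CLASSES}
        else:
            self.dnds = {}

    @property
    def D_nonsyn(self) -> float:
        return float(sum(self.D[x] for x in SELECTION_CLASSES))

    @property
    def L_nonsyn(self) -> float:
        return float(sum(self.L[x] for x in SELECTION_CLASSES))

    @property
    def dN_pooled(self) -> float:
        return self.D_nonsyn / self.L_nonsyn

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": x,
                "D": self.D[x],
                "L": self.L[x],
                "dN": self.dN[x],
                "dN/dS": self.dnds.get(x, float("nan")),
            }
            for x in SELECTION_CLASSES
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            self.to_frame().to_csv(fh, sep="\t", index=False)
            fh.write(f"\n# D_syn\t{self.D_syn}\n# L_syn\t{self.L_syn}\n# dS\t{self.dS}\n")
            fh.write(f"# dS_defined\t{self.dS_defined}\n# delta_dnds\t{self.delta}\n")


def dnds_by_class(counts: SubstitutionCounts, opportunities: OpportunityTable) -> DivergenceTable:
    """Per-class dN(x) = D(x)/L(x) and dS = D_syn/L_syn.

    When D_syn = 0 the dN/dS ratios are undefined and the table is flagged
    (dS_defined = False); dN values are still reported. delta is filled in
    whenever any non-synonymous substitution exists.
    """
    table = DivergenceTable(
        D={x: float(counts.D(x)) for x in SELECTION_CLASSES},
        D_syn=float(counts.D_syn),
        L={x: opportunities.L(x) for x in SELECTION_CLASSES},
        L_syn=opportunities.L_syn,
    )
    if table.D_nonsyn > 0:
        table.delta = delta_dnds(table)
    return table


def delta_dnds(table: DivergenceTable) -> float:
    """Inflation of dN/dS attributable to B0 substitutions.

    delta = (dN/dS - dN(S0<1)/dS) / (dN/dS) = (dN - dN(S0<1)) / dN, where
    dN(S0<1) excludes B0 substitutions from the numerator while keeping the
    full non-synonymous opportunity. Both forms are computed and asserted
    equal; raises when no non-synonymous substitution exists.
    """
    if table.D_nonsyn <= 0:
        raise ValueError("delta(dN/dS) is undefined when dN = 0")
    dn = table.dN_pooled
    dn_excl = (table.D_nonsyn - table.D["B0"]) / table.L_nonsyn
    delta_dn = (dn - dn_excl) / dn
    if table.dS_defined:
        r, r_excl = dn / table.dS, dn_excl / table.dS
        delta_ratio = (r - r_excl) / r
        assert abs(delta_ratio - delta_dn) < 1e-12
    return float(delta_dn)
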