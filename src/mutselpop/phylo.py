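"""Phylogenies, codon alignments, pruning likelihoods and per-site fitness estimation.

The likelihood engine is Felsenstein pruning over the 61 sense codons with
gaps treated as missing data. Because the mutation-selection generator is
reversible whenever the nucleotide model is, transition matrices are applied
through a symmetrized eigendecomposition: with D = diag(sqrt(pi)),
B = D q D^-1 is symmetric, so expm(q t) x = D^-1 U exp(L t) U' D x costs two
matrix-vector products per branch after one eigh per candidate rate matrix.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import dendropy
import scipy.optimize
from Bio import SeqIO

from ._codes import CODON_INDEX, N_CODONS, CODON_AA, SENSE_CODONS, STOP_CODONS
from .mutation import NucleotideMutationModel
from .mutsel import (
    SiteFitnessProfile,
    build_site_rate_matrix,
    stationary_from_profile,
    CodonRateMatrix,
)


class Phylogeny:
    """A rooted tree with branch lengths in expected substitutions per site.

    Stored as parallel arrays in postorder (root last): ``children[k]`` lists
    child node ids and ``edge_length[k]`` is the branch above node k.
    """

    def __init__(self, children, edge_length, labels):
        self.children = children
        self.edge_length = np.asarray(edge_length, dtype=float)
        if np.any(self.edge_length < 0):
            raise ValueError("branch lengths must be non-negative")
        self.labels = labels  # node id -> leaf label (internal nodes: None)
        self.n_nodes = len(children)
        self.leaf_ids = {lab: k for k, lab in enumerate(labels) if lab is not None}
        if len(self.leaf_ids) != sum(lab is not None for lab in labels):
            raise ValueError("leaf labels must be unique")

    @property
    def leaf_labels(self):
        return list(self.leaf_ids)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def scaled(self, factor: float) -> "Phylogeny":
        return Phylogeny(self.children, self.edge_length * factor, list(self.labels))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): k for k, nd in enumerate(nodes)}
        children = [[index[id(c)] for c in nd.child_nodes()] for nd in nodes]
        edge = [nd.edge.length or 0.0 for nd in nodes]
        labels = [nd.taxon.label if nd.taxon is not None and nd.is_leaf() else None for nd in nodes]
        return cls(children, edge, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def rec(k):
            if not self.children[k]:
                return f"{self.labels[k]}:{self.edge_length[k]:g}"
            inner = ",".join(rec(c) for c in self.children[k])
            return f"({inner}):{self.edge_length[k]:g}"

        return rec(self.root).rsplit(":", 1)[0] + ";"

    @classmethod
    def star(cls, labels, branch_length: float) -> "Phylogeny":
        n = len(labels)
        children = [[] for _ in range(n)] + [list(range(n))]
        edge = [branch_length] * n + [0.0]
        return cls(children, edge, list(labels) + [None])

    @classmethod
    def balanced(cls, n_leaves: int, height: float, prefix: str = "t") -> "Phylogeny":
        """Balanced binary tree with ultrametric leaves at the given height."""
        import math

        depth = math.ceil(math.log2(max(n_leaves, 2)))
        edge_len = height / depth
        newick = _balanced_newick(n_leaves, depth, edge_len, prefix)
        return cls.from_newick(newick)


def _balanced_newick(n_leaves, depth, edge_len, prefix):
    leaves = [f"{prefix}{i}" for i in range(n_leaves)]

    def build(items, d):
        if len(items) == 1:
            extra = edge_len * d
            return f"{items[0]}:{extra:g}"
        half = (len(items) + 1) // 2
        return f"({build(items[:half], d - 1)},{build(items[half:], d - 1)}):{edge_len:g}"

    return build(leaves, depth) + ";"


@dataclass
class CodonAlignment:
    """Codon alignment as a (taxa, sites) matrix of sense-codon indices.

    Gaps, ambiguous codons and masked codons are -1 (missing data). In-frame
    stop codons in ungapped positions are rejected.
    """

    taxa: list
    codons: np.ndarray  # (T, S) int, -1 missing

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix must be (n_taxa, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def gap_fraction(self) -> np.ndarray:
        return (self.codons < 0).mean(axis=0)

    def filter_gap_sites(self, max_gap_frac: float = 0.1):
        """Drop sites with more than the given fraction of gaps.

        Returns (filtered alignment, boolean mask of retained sites).
        """
        keep = self.gap_fraction() <= max_gap_frac
        return CodonAlignment(self.taxa, self.codons[:, keep]), keep

    @classmethod
    def from_sequences(cls, sequences: dict) -> "CodonAlignment":
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned (equal length)")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length must be divisible by 3")
        n_sites = length // 3
        mat = np.full((len(taxa), n_sites), -1, dtype=np.int64)
        for t, tax in enumerate(taxa):
            seq = sequences[tax].upper().replace("U", "T")
            for s in range(n_sites):
                codon = seq[3 * s: 3 * s + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"in-frame stop codon {codon} in {tax} at codon site {s}")
                mat[t, s] = CODON_INDEX.get(codon, -1)
        return cls(taxa, mat)

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, tax in enumerate(self.taxa):
                seq = "".join(
                    SENSE_CODONS[c] if c >= 0 else "---" for c in self.codons[t]
                )
                fh.write(f">{tax}\n{seq}\n")


# -- pruning ---------------------------------------------------------------

class _Propagator:
    """expm(q t) @ x via symmetrized eigendecomposition of a reversible q."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(np.maximum(pi, 1e-300))
        B = (q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        self.lam, self.U, self.d = lam, U, d

    def apply(self, t: float, partials: np.ndarray) -> np.ndarray:
        """Rows of ``partials`` are per-site conditional likelihood vectors."""
        e = np.exp(self.lam * t)
        X = (partials * self.d) @ self.U
        return np.maximum(((X * e) @ self.U.T) / self.d, 0.0)


def _prune(tree: Phylogeny, prop: _Propagator, pi: np.ndarray, leaf_partials) -> np.ndarray:
    """Log-likelihood per site. ``leaf_partials``: node id -> (S, 61) array."""
    n_sites = next(iter(leaf_partials.values())).shape[0]
    partial = {}
    logscale = np.zeros(n_sites)
    for k in range(tree.n_nodes):
        if not tree.children[k]:
            partial[k] = leaf_partials[k]
            continue
        acc = np.ones((n_sites, N_CODONS))
        for c in tree.children[k]:
            acc = acc * prop.apply(tree.edge_length[c], partial.pop(c))
        mx = acc.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        logscale += np.log(mx)
        partial[k] = acc / mx[:, None]
    lik = partial[tree.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def _leaf_partials(tree: Phylogeny, states: np.ndarray, taxa: list) -> dict:
    """One-hot leaf partials; missing states (-1) become all-ones rows."""
    out = {}
    eye = np.eye(N_CODONS)
    for t, tax in enumerate(taxa):
        if tax not in tree.leaf_ids:
            raise KeyError(f"unknown leaf label {tax!r}")
        s = states[t]
        part = np.ones((len(s), N_CODONS))
        obs = s >= 0
        part[obs] = eye[s[obs]]
        out[tree.leaf_ids[tax]] = part
    missing = set(tree.leaf_ids.values()) - set(out)
    if missing:
        n_sites = states.shape[1]
        for k in missing:
            out[k] = np.ones((n_sites, N_CODONS))
    return out


def pruning_loglik(tree: Phylogeny, matrix: CodonRateMatrix, column: dict) -> float:
    """Log-likelihood of one alignment column under a site rate matrix.

    ``column`` maps leaf labels to codon strings or sense-codon indices;
    missing leaves and gaps contribute all-ones partials. The root is
    weighted by the stationary distribution.
    """
    taxa = list(column)
    states = np.full((len(taxa), 1), -1, dtype=np.int64)
    for t, tax in enumerate(taxa):
        v = column[tax]
        if isinstance(v, str):
            states[t, 0] = CODON_INDEX.get(v.upper(), -1)
        elif v is not None:
            states[t, 0] = int(v)
    pi = matrix.stationary
    prop = _Propagator(matrix.q, pi)
    lp = _prune(tree, prop, pi, _leaf_partials(tree, states, taxa))
    return float(lp[0])


# -- branch-length scale under a neutral codon model -----------------------

def neutral_codon_matrix(mu: NucleotideMutationModel) -> CodonRateMatrix:
    """Mutation-only codon generator (all amino-acid fitnesses equal)."""
    return build_site_rate_matrix(mu, SiteFitnessProfile(site=-1, F=np.zeros(20)))


def alignment_loglik(tree: Phylogeny, matrix: CodonRateMatrix, alignment: CodonAlignment) -> float:
    pi = matrix.stationary
    prop = _Propagator(matrix.q, pi)
    parts = _leaf_partials(tree, alignment.codons, alignment.taxa)
    return float(_prune(tree, prop, pi, parts).sum())


def fit_branch_scale(
    alignment: CodonAlignment,
    tree: Phylogeny,
    mu: NucleotideMutationModel,
    bounds: tuple = (1e-3, 1e3),
) -> Phylogeny:
    """Fit one multiplicative scale on all branch lengths.

    The likelihood is computed under the neutral (all-fitnesses-equal) codon
    matrix, whose synonymous flux carries the branch-length signal. Raises if
    the alignment has no variation (scale unidentifiable).
    """
    obs = alignment.codons
    varying = False
    for s in range(alignment.n_sites):
        col = obs[:, s]
        col = col[col >= 0]
        if col.size and not np.all(col == col[0]):
            varying = True
            break
    if not varying:
        raise ValueError("alignment has no variation: branch scale is unidentifiable")
    matrix = neutral_codon_matrix(mu)
    pi = matrix.stationary
    prop = _Propagator(matrix.q, pi)
    parts = _leaf_partials(tree, obs, alignment.taxa)

    def negll(log_scale):
        scaled = tree.scaled(np.exp(log_scale))
        return -float(_prune(scaled, prop, pi, parts).sum())

    res = scipy.optimize.minimize_scalar(
        negll, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-4},
    )
    return tree.scaled(float(np.exp(res.x)))


# -- per-site fitness estimation -------------------------------------------

def estimate_site_profiles(
    alignment: CodonAlignment,
    tree: Phylogeny,
    mu: NucleotideMutationModel,
    penalty_weight: float = 0.1,
    pool_unobserved: bool = True,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 200,
) -> list:
    """Penalized per-site maximum-likelihood amino-acid fitness profiles.

    Each site's 20 log-fitnesses maximize the pruning log-likelihood minus a
    ridge penalty ``penalty_weight * sum(F**2)`` on the mean-centered vector,
    shrinking toward neutrality. With ``pool_unobserved`` (default), amino
    acids never observed at the site share a single fitness parameter: their
    separate values are held up only by the ridge, and pooling shrinks the
    optimization dimension to the number of observed amino acids. Multi-start
    bounded quasi-Newton; convergence status is recorded per profile.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for s in range(alignment.n_sites):
        col = alignment.codons[:, s]
        obs = col[col >= 0]
        if obs.size == 0:
            profiles.append(
                SiteFitnessProfile(site=s, F=np.zeros(20), converged=True, uninformative=True)
            )
            continue
        observed_aas = np.unique(CODON_AA[obs])
        if pool_unobserved:
            free = observed_aas
        else:
            free = np.arange(20)
        states = col.reshape(-1, 1)
        parts = _leaf_partials(tree, states, alignment.taxa)

        def negll(theta, _free=free, _parts=parts):
            F = np.zeros(20)
            F[_free] = theta
            F -= F.mean()
            pi = stationary_from_profile(mu, F)
            q = build_site_rate_matrix(mu, SiteFitnessProfile(site=-2, F=F)).q
            prop = _Propagator(q, pi)
            ll = _prune(tree, prop, pi, _parts)[0]
            return -ll + penalty_weight * float(np.sum(F**2))

        best = None
        for start in range(max(1, n_starts)):
            theta0 = np.zeros(len(free)) if start == 0 else rng.normal(0, 1, len(free))
            res = scipy.optimize.minimize(
                negll, theta0, method="L-BFGS-B",
                bounds=[(-25.0, 25.0)] * len(free),
                options={"maxiter": maxiter, "ftol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        F = np.zeros(20)
        F[free] = best.x
        profiles.append(SiteFitnessProfile(site=s, F=F, converged=bool(best.success)))
    return profiles
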