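"""From exome + SNP table to polarized, classified, opportunity-weighted SFS.

Conventions: exomes are arrays of sense-codon indices; SNP tables are pandas
DataFrames with columns gene, site (0-based codon index into the alignment),
ancestral_codon, derived_codon, derived_count, n, cpg_flag. Opportunities are
counted in nucleotide sites: L_tot = 3 * (codon sites), and each class's
share is its mutation-rate-weighted fraction of all non-stop changes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codes import CODON_AA, CODON_INDEX, SENSE_CODONS, NT_INDEX, NUCLEOTIDES
from .mutation import NucleotideMutationModel
from .mutsel import (
    CLASS_SYNONYMOUS,
    SELECTION_CLASSES,
    change_tables,
    classify_S0,
)
from .phylo import Phylogeny

SNP_COLUMNS = ["gene", "site", "ancestral_codon", "derived_codon", "derived_count", "n", "cpg_flag"]


@dataclass
class SiteFrequencySpectrum:
    """Derived-allele counts xi_1..xi_{n-1} with sample size n and opportunity L."""

    counts: np.ndarray
    n: int
    L: float
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n - 1,):
            raise ValueError("SFS must have n-1 frequency bins")
        if np.any(self.counts < 0) or self.L <= 0:
            raise ValueError("SFS counts must be >= 0 and L > 0")

    @property
    def segregating(self) -> float:
        return float(self.counts.sum())


@dataclass
class OpportunityTable:
    """Mutation-rate-weighted opportunity shares (Eqs of the opportunity scheme).

    L_syn = L_tot * mu_syn / mu_tot and L(x) = L_tot * mu(x) / mu_tot for each
    selection class x, with stop-gaining changes excluded from mu_tot so that
    L_syn + sum_x L(x) = L_tot holds exactly.
    """

    L_tot: float
    mu_tot: float
    mu_syn: float
    mu_x: dict
    dropped_stop_weight: float = 0.0

    @property
    def L_syn(self) -> float:
        return self.L_tot * self.mu_syn / self.mu_tot

    def L(self, x: str) -> float:
        return self.L_tot * self.mu_x[x] / self.mu_tot

    def P(self, x: str) -> float:
        tot = sum(self.mu_x.values())
        return self.mu_x[x] / tot

    @property
    def class_priors(self) -> dict:
        return {x: self.P(x) for x in SELECTION_CLASSES}

    def check(self, atol: float = 1e-9) -> None:
        total = self.L_syn + sum(self.L(x) for x in SELECTION_CLASSES)
        assert abs(total - self.L_tot) < atol * max(1.0, self.L_tot)
        assert abs(sum(self.class_priors.values()) - 1.0) < 1e-12
        assert self.mu_syn >= 0 and all(v >= 0 for v in self.mu_x.values())


@dataclass
class AncestralExome:
    """Most-likely ancestral codon per site with its polarization probability."""

    codons: np.ndarray
    polarization_prob: np.ndarray | None = None

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.polarization_prob is None:
            self.polarization_prob = np.ones(len(self.codons))
        self.polarization_prob = np.asarray(self.polarization_prob, dtype=float)
        if np.any((self.polarization_prob < 0) | (self.polarization_prob > 1)):
            raise ValueError("polarization probabilities must lie in [0, 1]")


class PolymorphismSet:
    """Bi-allelic single-nucleotide SNP records indexed to alignment coordinates."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in SNP_COLUMNS if c not in table.columns and c != "cpg_flag"]
        if missing:
            raise ValueError(f"SNP table missing columns: {missing}")
        table = table.copy()
        if "cpg_flag" not in table.columns:
            table["cpg_flag"] = 0
        i, n = table["derived_count"].to_numpy(), table["n"].to_numpy()
        if np.any((i < 1) | (i > n - 1)):
            raise ValueError("derived counts must satisfy 1 <= i <= n-1")
        for col in ("ancestral_codon", "derived_codon"):
            bad = ~table[col].isin(CODON_INDEX)
            if bad.any():
                raise ValueError(f"non-sense codons in column {col}")
        anc = table["ancestral_codon"].map(CODON_INDEX).to_numpy()
        der = table["derived_codon"].map(CODON_INDEX).to_numpy()
        ndiff = np.array(
            [sum(a != b for a, b in zip(SENSE_CODONS[x], SENSE_CODONS[y])) for x, y in zip(anc, der)]
        )
        if np.any(ndiff != 1):
            raise ValueError("every SNP must be a single-nucleotide codon change")
        self.table = table.reset_index(drop=True)

    def __len__(self):
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "PolymorphismSet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# -- polarization ----------------------------------------------------------

POLARIZATION_THRESHOLD = 0.99


@dataclass
class PolarizationResult:
    ancestral: str | None
    probability: float
    dropped: bool
    reason: str = ""


def _nt_pruning_likelihood(tree: Phylogeny, mu: NucleotideMutationModel, states: dict) -> float:
    """Likelihood of nucleotide leaf states (None = missing) on a small tree."""
    pi = mu.equilibrium_freqs
    partial = {}
    for k in range(tree.n_nodes):
        if not tree.children[k]:
            label = tree.labels[k]
            s = states.get(label)
            v = np.ones(4) if s is None else np.eye(4)[NT_INDEX[s]]
            partial[k] = v
            continue
        acc = np.ones(4)
        for c in tree.children[k]:
            P = mu.transition_matrix(tree.edge_length[c])
            acc = acc * (P @ partial.pop(c))
        partial[k] = acc
    return float(partial[tree.root] @ pi)


def polarize(
    alleles: tuple,
    outgroup_states: dict,
    tree: Phylogeny,
    mu: NucleotideMutationModel,
    focal_label: str = "focal",
    threshold: float = POLARIZATION_THRESHOLD,
) -> PolarizationResult:
    """Ancestral-allele assignment from three outgroups on a 4-taxon tree.

    Each of the two segregating alleles is tried as the state at the base of
    the focal branch; the pruning likelihood of the outgroup pattern under
    the neutral nucleotide model gives the posterior (uniform prior over the
    two alleles). SNPs whose best allele falls below the probability
    threshold are dropped, as are sites with no outgroup information.
    """
    a1, a2 = (a.upper() for a in alleles)
    if all(v is None for v in outgroup_states.values()):
        return PolarizationResult(None, 0.5, True, "no_outgroup_data")
    liks = []
    for allele in (a1, a2):
        states = dict(outgroup_states)
        states[focal_label] = allele
        liks.append(_nt_pruning_likelihood(tree, mu, states))
    total = liks[0] + liks[1]
    if total <= 0:
        return PolarizationResult(None, 0.5, True, "zero_likelihood")
    p1 = liks[0] / total
    best, p = (a1, p1) if p1 >= 0.5 else (a2, 1 - p1)
    if p < threshold:
        return PolarizationResult(best, p, True, "below_threshold")
    return PolarizationResult(best, p, False)


def reconstruct_ancestral_exome(reference: np.ndarray, snps: PolymorphismSet) -> AncestralExome:
    """Replace the reference codon by the ancestral allele at every SNP site.

    Raises on conflicting assignments at one site (tri-allelic leak).
    """
    codons = np.asarray(reference, dtype=np.int64).copy()
    assigned = {}
    for row in snps.table.itertuples(index=False):
        site = int(row.site)
        anc = CODON_INDEX[row.ancestral_codon]
        if site in assigned and assigned[site] != anc:
            raise ValueError(f"conflicting ancestral codons at site {site}")
        assigned[site] = anc
        codons[site] = anc
    return AncestralExome(codons=codons)


# -- opportunities and spectra ---------------------------------------------

def mutational_opportunities(
    exome,
    mu: NucleotideMutationModel,
    Fmat: np.ndarray,
    exclude_sites: np.ndarray | None = None,
) -> OpportunityTable:
    """Mutation-rate-weighted opportunities over all single-nucleotide changes.

    Enumerates the 9 changes of every codon of the (ancestral) exome, drops
    stop-gaining changes, and accumulates mu-weights into the synonymous
    share and each selection class by the S0 of the change. ``exclude_sites``
    (boolean mask over codon sites, e.g. a CpG flag, or an array of site
    indices) removes whole sites from both L_tot and the weights.
    """
    codons = exome.codons if isinstance(exome, AncestralExome) else np.asarray(exome)
    Fmat = np.asarray(Fmat, dtype=float)
    if Fmat.shape != (len(codons), 20):
        raise ValueError("fitness matrix must cover every exome site")
    if exclude_sites is not None:
        excl = np.asarray(exclude_sites)
        if excl.dtype == bool:
            if excl.shape != (len(codons),):
                raise ValueError("boolean exclude_sites must have one entry per site")
            keep = ~excl
        else:
            keep = np.ones(len(codons), dtype=bool)
            keep[excl.astype(np.int64)] = False
        codons, Fmat = codons[keep], Fmat[keep]
    tables = change_tables(codons, Fmat, mu)
    w = tables["mu_weight"]
    from ._codes import NEI_FROM_NT, NEI_TO_NT

    raw = mu.rates[NEI_FROM_NT[codons], NEI_TO_NT[codons]]
    dropped_stop = float(raw[tables["is_stop"]].sum())
    mu_syn = float(w[tables["is_syn"]].sum())
    nonsyn = ~tables["is_syn"] & ~tables["is_stop"]
    classes = classify_S0(tables["dF"])
    mu_x = {}
    for x in SELECTION_CLASSES:
        mu_x[x] = float(w[nonsyn & (classes == x)].sum())
    mu_tot = mu_syn + sum(mu_x.values())
    table = OpportunityTable(
        L_tot=3.0 * len(codons),
        mu_tot=mu_tot,
        mu_syn=mu_syn,
        mu_x=mu_x,
        dropped_stop_weight=dropped_stop,
    )
    table.check()
    return table


def classify_snps(snps: PolymorphismSet, Fmat: np.ndarray) -> pd.DataFrame:
    """Attach S0 and selection class (reported ancestral -> derived) to SNPs."""
    t = snps.table.copy()
    anc = t["ancestral_codon"].map(CODON_INDEX).to_numpy(dtype=int)
    der = t["derived_codon"].map(CODON_INDEX).to_numpy(dtype=int)
    sites = t["site"].to_numpy(dtype=int)
    aa_a, aa_d = CODON_AA[anc], CODON_AA[der]
    syn = aa_a == aa_d
    S0 = np.where(syn, 0.0, Fmat[sites, aa_d] - Fmat[sites, aa_a])
    cls = classify_S0(S0)
    cls[syn] = CLASS_SYNONYMOUS
    t["S0"] = S0
    t["selection_class"] = cls
    return t


def build_sfs(
    snps: PolymorphismSet,
    opportunities: OpportunityTable,
    Fmat: np.ndarray,
    exclude_cpg: bool = False,
    cpg_opportunities: OpportunityTable | None = None,
    n: int | None = None,
) -> dict:
    """One SFS per selection class plus the synonymous spectrum.

    With ``exclude_cpg``, CpG-flagged SNPs are dropped and the opportunities
    recomputed on the unflagged sites must be supplied. ``n`` is inferred
    from the SNP table unless given; an empty table requires an explicit n.
    """
    t = classify_snps(snps, Fmat)
    ns = t["n"].unique()
    if len(ns) > 1:
        raise ValueError(f"mixed sample sizes in SNP table: {sorted(ns)}")
    if len(ns) and n is not None and int(ns[0]) != n:
        raise ValueError(f"SNP table sample size {int(ns[0])} != requested n={n}")
    if len(ns):
        n = int(ns[0])
    elif n is None:
        raise ValueError("empty SNP table: pass the sample size n explicitly")
    if exclude_cpg:
        if cpg_opportunities is None:
            raise ValueError("exclude_cpg requires opportunities recomputed on unflagged sites")
        t = t[t["cpg_flag"] == 0]
        opportunities = cpg_opportunities
    out = {}
    for label in (CLASS_SYNONYMOUS,) + SELECTION_CLASSES:
        sub = t[t["selection_class"] == label]
        counts = np.bincount(sub["derived_count"].to_numpy(dtype=int), minlength=n)[1:n]
        L = opportunities.L_syn if label == CLASS_SYNONYMOUS else opportunities.L(label)
        out[label] = SiteFrequencySpectrum(counts=counts.astype(float), n=n, L=L, label=label)
    return out


def subsample_sfs(sfs: SiteFrequencySpectrum, m: int, method: str = "exact", seed: int = 0) -> SiteFrequencySpectrum:
    """Hypergeometric subsampling of an SFS from n to m chromosomes.

    The default deterministic variant distributes each count over the exact
    hypergeometric probabilities (monomorphic outcomes 0 and m dropped); the
    sampling variant draws without replacement with a seed.
    """
    from scipy.stats import hypergeom

    if m < 2:
        raise ValueError("subsample size must be >= 2")
    if m > sfs.n:
        raise ValueError("cannot subsample to more chromosomes than sampled")
    if m == sfs.n:
        return sfs
    n = sfs.n
    new = np.zeros(m - 1)
    if method == "exact":
        for i in range(1, n):
            if sfs.counts[i - 1] == 0:
                continue
            j = np.arange(1, m)
            p = hypergeom.pmf(j, n, i, m)
            new += sfs.counts[i - 1] * p
    elif method == "sample":
        rng = np.random.default_rng(seed)
        for i in range(1, n):
            c = int(sfs.counts[i - 1])
            if c == 0:
                continue
            draws = rng.hypergeometric(i, n - i, m, size=c)
            keep = draws[(draws > 0) & (draws < m)]
            new += np.bincount(keep, minlength=m)[1:m]
    else:
        raise ValueError("method must be 'exact' or 'sample'")
    return SiteFrequencySpectrum(counts=new, n=m, L=sfs.L, label=sfs.label)


def watterson_theta(sfs_syn: SiteFrequencySpectrum, L_syn: float | None = None) -> float:
    """Watterson's theta from the synonymous SFS: sum(xi) / (a_{n-1} L_syn)."""
    if sfs_syn.n < 2:
        raise ValueError("need n >= 2")
    L = sfs_syn.L if L_syn is None else L_syn
    if L <= 0:
        raise ValueError("L_syn must be > 0")
    a = np.sum(1.0 / np.arange(1, sfs_syn.n))
    return float(sfs_syn.segregating / (a * L))


def ne_estimate(theta_s: float, u: float) -> float:
    """Effective population size Ne = theta_S / (4u)."""
    return theta_s / (4.0 * u)
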