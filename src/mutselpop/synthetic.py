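"""Synthetic fitness landscapes, alignments, terminal-branch histories and
population polymorphism with known ground truth.

The generator emulates the study conditions end to end: site-specific
20-amino-acid fitness profiles, codon evolution under the mutation-selection
generator along a tree, a terminal branch on which a configurable fraction
of sites has its landscape redrawn (the adaptive component), and Poisson
random field polymorphism with configurable mispolarization and a CpG-like
hypermutability flag. Every random draw flows from one master seed through
named substreams, so bundles are reproducible.

Scaling conventions: ``u`` is the mutation rate per nucleotide site per
generation and theta = 4 Ne u. The relative nucleotide rate matrix mu is
rescaled so that its equilibrium total rate is 1, making the absolute rate
of a specific change u * mu_ab / total_rate(mu).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codes import CODON_AA, N_CODONS, SENSE_CODONS
from .mutation import NucleotideMutationModel
from .mutsel import (
    CLASS_SYNONYMOUS,
    SELECTION_CLASSES,
    SiteFitnessProfile,
    change_tables,
    classify_S0,
    profiles_to_matrix,
    stationary_matrix,
)
from .phylo import CodonAlignment, Phylogeny
from .popgen import PolymorphismSet, SiteFrequencySpectrum
from .prf import sojourn_grid

_STREAMS = {
    "landscape": 1,
    "tree_sim": 2,
    "branch_sim": 3,
    "polymorphism": 4,
    "polarization_noise": 5,
    "cpg": 6,
    "shift": 7,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic dataset.

    Defaults mirror the mammalian setting: pedigree-scale mutation rate
    u = 7.24e-9 per site per generation and Ne chosen so that synonymous
    diversity theta = 4 Ne u is about 0.01, with spectra at n = 16
    chromosomes (the subsampling depth used throughout).
    """

    tree: Phylogeny
    mu: NucleotideMutationModel
    profiles: list
    Ne: float = 3.45e5
    u: float = 7.24e-9
    n: int = 16
    shift_fraction: float = 0.0
    mispolarization_rate: float = 0.0
    cpg_fraction: float = 0.0
    cpg_multiplier: float = 1.0
    concentration: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must lie in [0, 1]")
        if not (0.0 <= self.mispolarization_rate <= 1.0):
            raise ValueError("mispolarization_rate must lie in [0, 1]")
        if min(self.Ne, self.u, self.cpg_multiplier) < 0 or self.n < 2:
            raise ValueError("rates must be >= 0 and n >= 2")

    @property
    def theta(self) -> float:
        return 4.0 * self.Ne * self.u

    @property
    def Fmat(self) -> np.ndarray:
        return profiles_to_matrix(self.profiles)

    @property
    def n_sites(self) -> int:
        return len(self.profiles)


def sample_fitness_landscape(n_sites: int, concentration: float, seed: int, floor: float = 1e-10) -> list:
    """Site profiles as log symmetric-Dirichlet draws, gauge-normalized.

    Small concentration gives highly constrained sites (one or few amino
    acids dominate); large concentration approaches neutrality (all F -> 0).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    p = rng.dirichlet(np.full(20, concentration), size=n_sites)
    F = np.log(np.maximum(p, floor))
    F = F - F.mean(axis=1, keepdims=True)
    return [SiteFitnessProfile._from_validated(i, F[i]) for i in range(n_sites)]


# -- branch-wise codon evolution -------------------------------------------

def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """One draw per row of a (k, m) probability matrix."""
    c = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * c[:, -1]
    return (u[:, None] > c).sum(axis=1)


def _evolve_branch(codons, Fmat, mu, length, rng, rate_mult=None):
    """Gillespie simulation of every site along one branch (vectorized).

    Returns (end codons, events) where events is a list of
    (site, from_codon, to_codon, time) tuples in branch time.
    """
    codons = np.asarray(codons, dtype=np.int64).copy()
    L = len(codons)
    remaining = np.full(L, float(length))
    elapsed = np.zeros(L)
    active = np.arange(L)
    events = []
    while active.size:
        ct = change_tables(codons[active], Fmat[active], mu)
        rates = ct["rate"]
        if rate_mult is not None:
            rates = rates * rate_mult[active][:, None]
        total = rates.sum(axis=1)
        wait = rng.exponential(1.0, active.size) / np.maximum(total, 1e-300)
        hit = wait < remaining[active]
        hit_sites = active[hit]
        if hit_sites.size:
            j = _sample_categorical(rng, rates[hit])
            new = ct["target"][hit, j]
            t_ev = elapsed[hit_sites] + wait[hit]
            for s, a, b, t in zip(hit_sites, codons[hit_sites], new, t_ev):
                events.append((int(s), int(a), int(b), float(t)))
            remaining[hit_sites] -= wait[hit]
            elapsed[hit_sites] = t_ev
            codons[hit_sites] = new
        active = hit_sites
    return codons, events


def simulate_alignment(scenario: SimulationScenario, rng=None, return_node_states: bool = False):
    """Evolve every site along the whole tree under the mutation-selection model.

    Root codons are drawn from each site's stationary distribution. Returns
    (CodonAlignment, event DataFrame) and optionally the internal node
    states. The event log has columns node, site, from_codon, to_codon,
    time, S0 and selection_class (classified on the simulating landscape).
    """
    if rng is None:
        rng = _stream(scenario.seed, "tree_sim")
    tree, mu, Fmat = scenario.tree, scenario.mu, scenario.Fmat
    pi = stationary_matrix(mu, Fmat)
    states = {tree.root: _sample_categorical(rng, pi)}
    all_events = []
    order = list(range(tree.n_nodes))[::-1]  # root first (postorder reversed)
    for k in order:
        for c in tree.children[k]:
            end, ev = _evolve_branch(states[k], Fmat, mu, tree.edge_length[c], rng)
            states[c] = end
            all_events.extend((c, *e) for e in ev)
    rows = np.array([tree.leaf_ids[lab] for lab in tree.leaf_labels])
    aln = CodonAlignment(tree.leaf_labels, np.stack([states[r] for r in rows]))
    events = _event_frame(all_events, Fmat)
    if return_node_states:
        return aln, events, states
    return aln, events


def _event_frame(events, Fmat) -> pd.DataFrame:
    df = pd.DataFrame(events, columns=["node", "site", "from_codon", "to_codon", "time"])
    if len(df):
        aa_a = CODON_AA[df["from_codon"].to_numpy()]
        aa_b = CODON_AA[df["to_codon"].to_numpy()]
        syn = aa_a == aa_b
        S0 = np.where(syn, 0.0, Fmat[df["site"].to_numpy(), aa_b] - Fmat[df["site"].to_numpy(), aa_a])
        cls = classify_S0(S0)
        cls[syn] = CLASS_SYNONYMOUS
        df["S0"] = S0
        df["selection_class"] = cls
    else:
        df["S0"] = np.zeros(0)
        df["selection_class"] = np.zeros(0, dtype=object)
    return df


@dataclass
class TerminalBranchResult:
    extant: np.ndarray             # extant exome codons
    records: pd.DataFrame          # per-event: site, codons, S_true, S0, classes, shifted
    Fmat_current: np.ndarray       # post-shift (true) landscape
    shifted: np.ndarray            # boolean mask of shifted sites


def simulate_terminal_branch(
    scenario: SimulationScenario,
    ancestral_exome: np.ndarray,
    branch_length: float,
    rng=None,
    cpg_mask: np.ndarray | None = None,
) -> TerminalBranchResult:
    """Evolve the focal terminal branch, redrawing shifted sites' landscapes.

    For the ``shift_fraction`` of sites drawn here, a fresh profile replaces
    the old one before simulation: the true selection coefficient of every
    event uses the new landscape while its S0 label uses the old one.
    """
    ancestral_exome = np.asarray(ancestral_exome, dtype=np.int64)
    if len(ancestral_exome) != scenario.n_sites:
        raise ValueError("ancestral exome size does not match profiles")
    if rng is None:
        rng = _stream(scenario.seed, "branch_sim")
    shift_rng = _stream(scenario.seed, "shift")
    Fold = scenario.Fmat
    shifted = shift_rng.random(scenario.n_sites) < scenario.shift_fraction
    Fnew = Fold.copy()
    if shifted.any():
        redraw = sample_fitness_landscape(int(shifted.sum()), scenario.concentration, shift_rng)
        Fnew[shifted] = profiles_to_matrix(redraw)
    mult = None
    if cpg_mask is not None and scenario.cpg_multiplier != 1.0:
        mult = np.where(cpg_mask, scenario.cpg_multiplier, 1.0)
    extant, events = _evolve_branch(ancestral_exome, Fnew, scenario.mu, branch_length, rng, rate_mult=mult)
    df = _event_frame([(0, *e) for e in events], Fnew).drop(columns=["node"])
    df = df.rename(columns={"S0": "S_true", "selection_class": "true_class"})
    if len(df):
        sites = df["site"].to_numpy()
        aa_a = CODON_AA[df["from_codon"].to_numpy()]
        aa_b = CODON_AA[df["to_codon"].to_numpy()]
        syn = aa_a == aa_b
        S0 = np.where(syn, 0.0, Fold[sites, aa_b] - Fold[sites, aa_a])
        cls = classify_S0(S0)
        cls[syn] = CLASS_SYNONYMOUS
        df["S0"] = S0
        df["selection_class"] = cls
        df["shifted"] = shifted[sites]
    else:
        df["S0"] = np.zeros(0)
        df["selection_class"] = np.zeros(0, dtype=object)
        df["shifted"] = np.zeros(0, dtype=bool)
    return TerminalBranchResult(extant=extant, records=df, Fmat_current=Fnew, shifted=shifted)


# -- polymorphism -----------------------------------------------------------

def _change_intensities(scenario, exome, Fmat_true, Fmat_classify, cpg_mask):
    """Per-change PRF intensity theta_c, true S, classify S0 and metadata."""
    mu = scenario.mu
    ct_true = change_tables(exome, Fmat_true, mu)
    ct_cls = change_tables(exome, Fmat_classify, mu)
    scale = scenario.theta / mu.total_rate
    theta_c = scale * ct_true["mu_weight"]
    if cpg_mask is not None and scenario.cpg_multiplier != 1.0:
        theta_c = theta_c * np.where(cpg_mask, scenario.cpg_multiplier, 1.0)[:, None]
    return {
        "theta": theta_c,
        "S_true": ct_true["dF"],
        "S0": ct_cls["dF"],
        "is_syn": ct_true["is_syn"],
        "is_stop": ct_true["is_stop"],
        "target": ct_true["target"],
    }


@dataclass
class GroundTruth:
    """Generative truth for scoring: per-SNP records and exact oracle tables."""

    snp_records: pd.DataFrame | None
    joint_mass: pd.DataFrame       # mu-weighted mass: rows S0 class, cols true class
    class_priors: dict             # P[x] among non-synonymous opportunity
    substitutions: pd.DataFrame | None = None
    ancestral_exome: np.ndarray | None = None

    def oracle_posterior(self, x: str, true: str) -> float:
        row = self.joint_mass.loc[x]
        return float(row[true] / row.sum()) if row.sum() > 0 else float("nan")

    def oracle_recall(self, true: str = "B") -> float:
        """P[x0 | true], e.g. P[B0|B]: Bayes over the exact joint mass."""
        x0 = true + "0"
        col = self.joint_mass[true]
        return float(col[x0] / col.sum()) if col.sum() > 0 else float("nan")


def _truth_tables(intens) -> tuple:
    """Exact mu-weighted joint mass of (S0 class, true population class)."""
    nonsyn = ~intens["is_syn"] & ~intens["is_stop"]
    w = intens["theta"][nonsyn]
    cls0 = classify_S0(intens["S0"][nonsyn])
    cls_true = classify_S0(intens["S_true"][nonsyn])
    joint = pd.DataFrame(
        0.0, index=list(SELECTION_CLASSES), columns=["D", "N", "B"]
    )
    for x in SELECTION_CLASSES:
        mx = cls0 == x
        for t, tlab in zip(SELECTION_CLASSES, ["D", "N", "B"]):
            joint.loc[x, tlab] = float(w[mx & (cls_true == t)].sum())
    tot = joint.to_numpy().sum()
    priors = {x: float(joint.loc[x].sum() / tot) for x in SELECTION_CLASSES}
    return joint, priors


def simulate_polymorphism(
    scenario: SimulationScenario,
    extant_exome: np.ndarray,
    Fmat_true: np.ndarray | None = None,
    Fmat_classify: np.ndarray | None = None,
    cpg_mask: np.ndarray | None = None,
    rng=None,
    mode: str = "auto",
):
    """Poisson-random-field polymorphism on the extant exome.

    Every possible single-nucleotide change arises as an independent Poisson
    field with expected sampled-SFS intensity theta_c * H_i(S_true); counts
    are already thinned to n chromosomes by the sojourn weights (monomorphic
    outcomes excluded by construction). Mispolarization flips a SNP's
    reported ancestral/derived orientation (derived count i -> n-i) at the
    configured rate.

    Returns (PolymorphismSet | None, class SFS dict, GroundTruth). ``mode``:
    "detail" emits per-SNP records; "aggregate" Poisson-samples class-level
    SFS totals directly (exact in distribution, up to a dense-grid
    discretization of S); "auto" picks detail below 200k sites.
    """
    if scenario.n < 2:
        raise ValueError("sample size n must be >= 2")
    extant_exome = np.asarray(extant_exome, dtype=np.int64)
    if Fmat_true is None:
        Fmat_true = scenario.Fmat
    if Fmat_classify is None:
        Fmat_classify = scenario.Fmat
    if rng is None:
        rng = _stream(scenario.seed, "polymorphism")
    pol_rng = _stream(scenario.seed, "polarization_noise")
    if mode == "auto":
        mode = "detail" if len(extant_exome) <= 200_000 else "aggregate"
    intens = _change_intensities(scenario, extant_exome, Fmat_true, Fmat_classify, cpg_mask)
    joint, priors = _truth_tables(intens)
    grid = sojourn_grid(scenario.n)
    n = scenario.n
    valid = ~intens["is_stop"]

    if mode == "detail":
        idx_site, idx_j = np.nonzero(valid)
        S = intens["S_true"][idx_site, idx_j]
        lam = intens["theta"][idx_site, idx_j][:, None] * grid.interp(S)
        counts = rng.poisson(lam)
        c_idx, i_idx = np.nonzero(counts)
        reps = counts[c_idx, i_idx]
        c_idx = np.repeat(c_idx, reps)
        i_idx = np.repeat(i_idx, reps)
        sites = idx_site[c_idx]
        anc = extant_exome[sites]
        der = intens["target"][sites, idx_j[c_idx]]
        i = i_idx + 1
        flip = pol_rng.random(len(sites)) < scenario.mispolarization_rate
        rep_anc = np.where(flip, der, anc)
        rep_der = np.where(flip, anc, der)
        rep_i = np.where(flip, n - i, i)
        cpg = cpg_mask[sites].astype(int) if cpg_mask is not None else np.zeros(len(sites), dtype=int)
        table = pd.DataFrame(
            {
                "gene": "synthetic",
                "site": sites,
                "ancestral_codon": [SENSE_CODONS[c] for c in rep_anc],
                "derived_codon": [SENSE_CODONS[c] for c in rep_der],
                "derived_count": rep_i,
                "n": n,
                "cpg_flag": cpg,
            }
        )
        truth_records = table.copy()
        truth_records["S_true"] = intens["S_true"][sites, idx_j[c_idx]]
        truth_records["S0"] = intens["S0"][sites, idx_j[c_idx]]
        truth_records["polarization_correct"] = ~flip
        snps = PolymorphismSet(table)
        sfs = _sfs_from_records(truth_records, intens, scenario, n)
        truth = GroundTruth(snp_records=truth_records, joint_mass=joint, class_priors=priors)
        return snps, sfs, truth

    if mode != "aggregate":
        raise ValueError("mode must be 'detail', 'aggregate' or 'auto'")

    labels = (CLASS_SYNONYMOUS,) + SELECTION_CLASSES
    lab_idx = {lab: k for k, lab in enumerate(labels)}
    G = len(grid.sgrid)
    W = np.zeros((len(labels), G))
    m_site, m_j = np.nonzero(valid)
    S = intens["S_true"][m_site, m_j]
    th = intens["theta"][m_site, m_j]
    syn = intens["is_syn"][m_site, m_j]
    cls = classify_S0(intens["S0"][m_site, m_j])
    cls[syn] = CLASS_SYNONYMOUS
    bins = grid.bin_index(S)
    cls_codes = np.array([lab_idx[c] for c in cls])
    np.add.at(W, (cls_codes, bins), th)
    E = W @ grid.H  # (labels, n-1)
    r = scenario.mispolarization_rate
    if r > 0:
        # a flipped SNP reports the mirrored count and the sign-reversed S0 class
        cls_rev = classify_S0(-intens["S0"][m_site, m_j])
        cls_rev[syn] = CLASS_SYNONYMOUS
        Wr = np.zeros_like(W)
        rev_codes = np.array([lab_idx[c] for c in cls_rev])
        np.add.at(Wr, (rev_codes, bins), th)
        E = (1.0 - r) * E + r * (Wr @ grid.H)[:, ::-1]
    xi = rng.poisson(E)
    sfs = {}
    for lab in labels:
        sfs[lab] = SiteFrequencySpectrum(
            counts=xi[lab_idx[lab]].astype(float), n=n, L=1.0, label=lab
        )
    truth = GroundTruth(snp_records=None, joint_mass=joint, class_priors=priors)
    return None, sfs, truth


def _sfs_from_records(records, intens, scenario, n):
    """Class SFS tallied from reported SNP orientations (L left at 1)."""
    labels = (CLASS_SYNONYMOUS,) + SELECTION_CLASSES
    aa = CODON_AA
    from ._codes import CODON_INDEX

    anc = records["ancestral_codon"].map(CODON_INDEX).to_numpy()
    der = records["derived_codon"].map(CODON_INDEX).to_numpy()
    sites = records["site"].to_numpy()
    Fc = intens["S0"]  # not used directly; recompute from reported direction below
    out = {}
    if len(records):
        syn = aa[anc] == aa[der]
        # reported S0: sign flips when orientation flipped
        S0_rep = np.where(records["polarization_correct"], records["S0"], -records["S0"])
        cls = classify_S0(S0_rep)
        cls[syn] = CLASS_SYNONYMOUS
        counts_i = records["derived_count"].to_numpy()
    for lab in labels:
        c = np.zeros(n - 1)
        if len(records):
            mask = cls == lab
            c = np.bincount(counts_i[mask], minlength=n)[1:n].astype(float)
        out[lab] = SiteFrequencySpectrum(counts=c, n=n, L=1.0, label=lab)
    return out


# -- shift-fraction calibration against the exact oracle --------------------

def oracle_recall_for_shift(
    exome: np.ndarray,
    Fmat: np.ndarray,
    Fmat_redrawn: np.ndarray,
    mu: NucleotideMutationModel,
    shift_fraction: float,
    theta_scale: float = 1.0,
) -> float:
    """Exact expected P[B0|B] when a fraction f of sites has a redrawn landscape.

    The joint mu-weighted mass is the (1-f, f) mixture of the stable table
    (true S = S0) and the fully-shifted table, so the oracle is a smooth
    function of f that can be root-found without simulation noise.
    """
    sc = _FakeScenario(mu, theta_scale)
    stable = _truth_tables(_change_intensities(sc, exome, Fmat, Fmat, None))[0]
    shifted = _truth_tables(_change_intensities(sc, exome, Fmat_redrawn, Fmat, None))[0]
    joint = (1.0 - shift_fraction) * stable + shift_fraction * shifted
    col = joint["B"]
    return float(col["B0"] / col.sum()) if col.sum() > 0 else float("nan")


class _FakeScenario:
    def __init__(self, mu, theta):
        self.mu = mu
        self.theta = theta
        self.cpg_multiplier = 1.0


def calibrate_shift_fraction(
    exome, Fmat, mu, target_recall: float, concentration: float, seed: int,
    branch_length: float = 0.0,
) -> float:
    """Shift fraction whose exact oracle P[B0|B] equals the target.

    With ``branch_length`` > 0 the shifted table accounts for adaptation
    along the terminal branch: the exome is first evolved under the redrawn
    landscape for that length (one Gillespie run), so shifted sites have
    partially climbed toward their new optima before polymorphism arises —
    exactly what the bundle generator produces. The joint mass stays linear
    in the shift fraction, so the root-find is exact and noise-free given
    the two tables.
    """
    import scipy.optimize

    rng = np.random.default_rng([int(seed), _STREAMS["shift"]])
    redraw = profiles_to_matrix(sample_fitness_landscape(len(exome), concentration, rng))
    sc = _FakeScenario(mu, 1.0)
    stable = _truth_tables(_change_intensities(sc, exome, Fmat, Fmat, None))[0]
    shifted_exome = np.asarray(exome, dtype=np.int64)
    if branch_length > 0:
        shifted_exome, _ = _evolve_branch(shifted_exome, redraw, mu, branch_length, rng)
    shifted = _truth_tables(_change_intensities(sc, shifted_exome, redraw, Fmat, None))[0]

    def recall(f):
        joint = (1.0 - f) * stable + f * shifted
        col = joint["B"]
        return float(col["B0"] / col.sum())

    f = scipy.optimize.brentq(lambda x: recall(x) - target_recall, 0.0, 1.0, xtol=1e-6)
    return float(f)


# -- forward Wright-Fisher oracle -------------------------------------------

def wright_fisher_sfs(
    S: float,
    theta: float,
    n: int,
    M: int = 200,
    burn_in_factor: float = 10.0,
    n_samples: int = 3000,
    sample_every: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Average sampled SFS from a forward haploid Wright-Fisher simulation.

    M chromosomes, genic selection sigma = S / (2M), influx theta/2 * ... per
    the haploid convention theta = 2 M u. Used as an independent oracle for
    the PRF expectation E[xi_i] = theta * H_i(S); expected counts are
    Rao-Blackwellized over the binomial sampling of n chromosomes.
    """
    from scipy.stats import binom

    rng = np.random.default_rng(seed)
    sigma = S / (2.0 * M)
    u = theta / (2.0 * M)
    freqs = np.zeros(0)
    expected = np.zeros(n - 1)
    total_gens = int(burn_in_factor * M) + n_samples * sample_every
    burn = int(burn_in_factor * M)
    taken = 0
    i = np.arange(1, n)
    for g in range(total_gens):
        if freqs.size:
            x = freqs * (1.0 + sigma) / (1.0 + sigma * freqs)
            k = rng.binomial(M, np.clip(x, 0.0, 1.0))
            freqs = k[(k > 0) & (k < M)] / M
        n_new = rng.poisson(M * u)
        if n_new:
            freqs = np.concatenate([freqs, np.full(n_new, 1.0 / M)])
        if g >= burn and (g - burn) % sample_every == 0:
            if freqs.size:
                pm = binom.pmf(i[None, :], n, freqs[:, None])
                expected += pm.sum(axis=0)
            taken += 1
    return expected / max(taken, 1)


# -- bundles ----------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Everything the pipeline consumes for one synthetic run, plus truth."""

    scenario: SimulationScenario
    alignment: CodonAlignment          # focal + outgroups (extant states)
    ancestral_exome: np.ndarray        # truth at the base of the terminal branch
    extant_exome: np.ndarray
    terminal: TerminalBranchResult
    snps: PolymorphismSet | None
    class_sfs: dict
    truth: GroundTruth
    cpg_mask: np.ndarray | None
    tree_events: pd.DataFrame


DEFAULT_BUNDLE_CONFIG = {
    "n_sites": 2000,
    "concentration": 0.05,
    "terminal_branch_length": 0.05,
    "outgroup_depths": (0.05, 0.1),
    "Ne": 3.45e5,
    "u": 7.24e-9,
    "n": 16,
    "shift_fraction": 0.0,
    "mispolarization_rate": 0.0,
    "cpg_fraction": 0.0,
    "cpg_multiplier": 1.0,
    "sim_mode": "auto",
}


def make_scenario_bundle(config: dict | None = None, seed: int = 0) -> ScenarioBundle:
    """Generate one complete synthetic dataset with ground truth.

    The focal species sits on a 4-taxon tree with three outgroups. The
    alignment is simulated to the base of the focal terminal branch under
    the stable landscape; the terminal branch itself may shift a fraction of
    site landscapes (the adaptive component); polymorphism arises on the
    extant exome from the current (post-shift) landscape while S0 labels use
    the stable one.
    """
    cfg = dict(DEFAULT_BUNDLE_CONFIG)
    cfg.update(config or {})
    tb = cfg["terminal_branch_length"]
    d1, d2 = cfg["outgroup_depths"]
    newick = (
        f"(((focal:{tb:g},o1:{tb:g}):{d1:g},o2:{tb + d1:g}):{d2:g},o3:{tb + d1 + d2:g});"
    )
    tree = Phylogeny.from_newick(newick)
    mu = cfg.get("mu") or NucleotideMutationModel.hky(2.0, (0.3, 0.2, 0.2, 0.3))
    profiles = sample_fitness_landscape(cfg["n_sites"], cfg["concentration"], _stream(seed, "landscape"))
    scenario = SimulationScenario(
        tree=tree,
        mu=mu,
        profiles=profiles,
        Ne=cfg["Ne"],
        u=cfg["u"],
        n=cfg["n"],
        shift_fraction=cfg["shift_fraction"],
        mispolarization_rate=cfg["mispolarization_rate"],
        cpg_fraction=cfg["cpg_fraction"],
        cpg_multiplier=cfg["cpg_multiplier"],
        concentration=cfg["concentration"],
        seed=seed,
    )
    cpg_mask = None
    if cfg["cpg_fraction"] > 0:
        cpg_mask = _stream(seed, "cpg").random(cfg["n_sites"]) < cfg["cpg_fraction"]
    aln, events, states = simulate_alignment(scenario, return_node_states=True)
    focal_leaf = tree.leaf_ids["focal"]
    parent = next(k for k in range(tree.n_nodes) if focal_leaf in tree.children[k])
    ancestral = states[parent]
    terminal = simulate_terminal_branch(scenario, ancestral, tb, cpg_mask=cpg_mask)
    # replace the focal row by the shifted-landscape terminal simulation
    codons = aln.codons.copy()
    codons[aln.taxa.index("focal")] = terminal.extant
    aln = CodonAlignment(aln.taxa, codons)
    snps, class_sfs, truth = simulate_polymorphism(
        scenario,
        terminal.extant,
        Fmat_true=terminal.Fmat_current,
        Fmat_classify=scenario.Fmat,
        cpg_mask=cpg_mask,
        mode=cfg["sim_mode"],
    )
    truth.substitutions = terminal.records
    truth.ancestral_exome = ancestral
    return ScenarioBundle(
        scenario=scenario,
        alignment=aln,
        ancestral_exome=ancestral,
        extant_exome=terminal.extant,
        terminal=terminal,
        snps=snps,
        class_sfs=class_sfs,
        truth=truth,
        cpg_mask=cpg_mask,
        tree_events=events,
    )
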