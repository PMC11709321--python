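"""Polarization, ancestral exomes, opportunities, spectra and diversity."""
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from mutselpop._codes import AA_INDEX, CODON_INDEX, SENSE_CODONS
from mutselpop.mutation import NucleotideMutationModel
from mutselpop.mutsel import SELECTION_CLASSES, SiteFitnessProfile, profiles_to_matrix
from mutselpop.phylo import Phylogeny
from mutselpop.popgen import (
    AncestralExome,
    PolymorphismSet,
    SiteFrequencySpectrum,
    build_sfs,
    classify_snps,
    mutational_opportunities,
    ne_estimate,
    polarize,
    reconstruct_ancestral_exome,
    subsample_sfs,
    watterson_theta,
)

FOUR_TAXON = "(((focal:0.02,o1:0.02):0.02,o2:0.04):0.04,o3:0.08);"


def _snp_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "site", "ancestral_codon", "derived_codon", "derived_count", "n"])


# -- polarization ------------------------------------------------------------

def test_concordant_outgroups_polarize_confidently(hky):
    tree = Phylogeny.from_newick(FOUR_TAXON)
    res = polarize(("A", "G"), {"o1": "A", "o2": "A", "o3": "A"}, tree, hky)
    assert not res.dropped
    assert res.ancestral == "A" and res.probability > 0.99


def test_uninformative_outgroups_dropped_at_half(hky):
    tree = Phylogeny.from_newick(FOUR_TAXON)
    res = polarize(("A", "G"), {"o1": None, "o2": None, "o3": None}, tree, hky)
    assert res.dropped and res.probability == 0.5
    assert res.reason == "no_outgroup_data"


def test_discordant_outgroups_on_long_branches_fall_below_threshold(uniform_mu):
    tree = Phylogeny.from_newick(
        "(((focal:2.0,o1:2.0):2.0,o2:2.0):2.0,o3:2.0);"
    )
    res = polarize(("A", "G"), {"o1": "A", "o2": "G", "o3": "A"}, tree, uniform_mu)
    assert res.dropped and res.reason == "below_threshold"
    # exhaustive 2-state posterior oracle
    from mutselpop.popgen import _nt_pruning_likelihood

    liks = []
    for allele in ("A", "G"):
        states = {"o1": "A", "o2": "G", "o3": "A", "focal": allele}
        liks.append(_nt_pruning_likelihood(tree, uniform_mu, states))
    assert res.probability == pytest.approx(max(liks) / sum(liks), rel=1e-12)


def test_bundle_polarization_probabilities_track_reconstruction(small_bundle, hky):
    """On a synthetic bundle, ML base-of-branch codons match truth >= 99%."""
    from mutselpop.divergence import reconstruct_branch_base

    rec = reconstruct_branch_base(small_bundle.alignment, small_bundle.scenario.tree, hky)
    acc = float(np.mean(rec.codons == small_bundle.ancestral_exome))
    assert acc >= 0.99


# -- ancestral exome ---------------------------------------------------------

def test_no_snps_leaves_exome_unchanged():
    ref = np.array([CODON_INDEX["ATG"], CODON_INDEX["GAA"]])
    snps = PolymorphismSet(_snp_frame([]))
    out = reconstruct_ancestral_exome(ref, snps)
    np.testing.assert_array_equal(out.codons, ref)


def test_reference_with_derived_allele_is_reverted():
    ref = np.array([CODON_INDEX["GAA"]])
    snps = PolymorphismSet(_snp_frame([("g", 0, "GAT", "GAA", 3, 16)]))
    out = reconstruct_ancestral_exome(ref, snps)
    assert out.codons[0] == CODON_INDEX["GAT"]


def test_conflicting_ancestral_codons_rejected():
    ref = np.array([CODON_INDEX["GAA"]])
    snps = PolymorphismSet(
        _snp_frame([("g", 0, "GAT", "GAA", 3, 16), ("g", 0, "GAC", "GAA", 2, 16)])
    )
    with pytest.raises(ValueError):
        reconstruct_ancestral_exome(ref, snps)


def test_snp_validation():
    with pytest.raises(ValueError):  # multi-nucleotide change
        PolymorphismSet(_snp_frame([("g", 0, "GAA", "CCA", 3, 16)]))
    with pytest.raises(ValueError):  # monomorphic count
        PolymorphismSet(_snp_frame([("g", 0, "GAA", "GAT", 16, 16)]))


# -- opportunities ------------------------------------------------------------

def test_flat_fitness_makes_everything_nearly_neutral(uniform_mu):
    exome = np.arange(20)
    Fmat = np.zeros((20, 20))
    opp = mutational_opportunities(exome, uniform_mu, Fmat)
    assert opp.P("N0") == 1.0
    assert opp.P("D0") == 0.0 and opp.P("B0") == 0.0


def test_single_codon_opportunities_match_hand_enumeration(hky):
    """Independent oracle: enumerate the 9 changes with Biopython's code."""
    codon = "TTA"  # Leu; has stop-gaining (TGA, TAA), synonymous and missense changes
    rng = np.random.default_rng(8)
    F = rng.normal(0, 2, 20)
    exome = np.array([CODON_INDEX[codon]])
    Fmat = (F - F.mean())[None, :]
    opp = mutational_opportunities(exome, hky, Fmat)

    from mutselpop._codes import NT_INDEX

    mu_syn = 0.0
    mu_x = {x: 0.0 for x in SELECTION_CLASSES}
    dropped = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            target = codon[:pos] + nt + codon[pos + 1:]
            w = hky.rates[NT_INDEX[codon[pos]], NT_INDEX[nt]]
            aa_from = str(Seq(codon).translate())
            aa_to = str(Seq(target).translate())
            if aa_to == "*":
                dropped += w
            elif aa_to == aa_from:
                mu_syn += w
            else:
                S0 = Fmat[0, AA_INDEX[aa_to]] - Fmat[0, AA_INDEX[aa_from]]
                cls = "D0" if S0 < -1 else "B0" if S0 > 1 else "N0"
                mu_x[cls] += w
    assert opp.mu_syn == pytest.approx(mu_syn, rel=1e-12)
    assert opp.dropped_stop_weight == pytest.approx(dropped, rel=1e-12)
    for x in SELECTION_CLASSES:
        assert opp.mu_x[x] == pytest.approx(mu_x[x], rel=1e-12)


@given(st.integers(0, 2**31 - 1))
def test_opportunity_conservation_identities(seed):
    rng = np.random.default_rng(seed)
    exome = rng.integers(0, 61, 40)
    Fmat = rng.normal(0, 2, (40, 20))
    Fmat -= Fmat.mean(axis=1, keepdims=True)
    mu = NucleotideMutationModel.hky(float(rng.uniform(1, 5)), rng.dirichlet(np.ones(4)))
    opp = mutational_opportunities(exome, mu, Fmat)
    total = opp.L_syn + sum(opp.L(x) for x in SELECTION_CLASSES)
    assert total == pytest.approx(opp.L_tot, rel=1e-9)
    assert sum(opp.P(x) for x in SELECTION_CLASSES) == pytest.approx(1.0, abs=1e-12)


def test_exclude_sites_mask_and_indices_agree(hky, rng):
    exome = rng.integers(0, 61, 30)
    Fmat = rng.normal(0, 2, (30, 20))
    Fmat -= Fmat.mean(axis=1, keepdims=True)
    mask = rng.random(30) < 0.3
    a = mutational_opportunities(exome, hky, Fmat, exclude_sites=mask)
    b = mutational_opportunities(exome, hky, Fmat, exclude_sites=np.nonzero(mask)[0])
    assert a.L_tot == b.L_tot and a.mu_syn == pytest.approx(b.mu_syn, rel=1e-12)


# -- spectra ------------------------------------------------------------------

def test_empty_snp_set_yields_zero_spectra_with_opportunities(hky, rng):
    exome = rng.integers(0, 61, 25)
    Fmat = rng.normal(0, 2, (25, 20))
    Fmat -= Fmat.mean(axis=1, keepdims=True)
    opp = mutational_opportunities(exome, hky, Fmat)
    snps = PolymorphismSet(_snp_frame([]))
    sfs = build_sfs(snps, opp, Fmat, n=16)
    for lab, s in sfs.items():
        assert s.segregating == 0 and s.L > 0
    with pytest.raises(ValueError):
        build_sfs(snps, opp, Fmat)  # n cannot be inferred from an empty table


def test_bundle_class_counts_match_truth_tallies(small_bundle, hky):
    """SNP classification on the true landscape reproduces the generator's spectra."""
    sc = small_bundle.scenario
    opp = mutational_opportunities(small_bundle.extant_exome, sc.mu, sc.Fmat)
    sfs = build_sfs(small_bundle.snps, opp, sc.Fmat)
    for lab, s in small_bundle.class_sfs.items():
        np.testing.assert_array_equal(sfs[lab].counts, s.counts)


def test_cpg_filter_drops_exactly_flagged_snps(hky):
    rows = [
        ("g", 0, "GAA", "GAT", 3, 16, 1),
        ("g", 1, "GAA", "GAT", 2, 16, 0),
        ("g", 2, "CTA", "CTG", 5, 16, 1),
    ]
    t = pd.DataFrame(rows, columns=["gene", "site", "ancestral_codon", "derived_codon", "derived_count", "n", "cpg_flag"])
    snps = PolymorphismSet(t)
    exome = np.array([CODON_INDEX["GAA"], CODON_INDEX["GAA"], CODON_INDEX["CTA"]])
    r = np.random.default_rng(4)
    Fmat = r.normal(0, 2, (3, 20))
    Fmat -= Fmat.mean(axis=1, keepdims=True)
    opp = mutational_opportunities(exome, hky, Fmat)
    opp_cpg = mutational_opportunities(exome, hky, Fmat, exclude_sites=np.array([True, False, True]))
    full = build_sfs(snps, opp, Fmat)
    filtered = build_sfs(snps, opp, Fmat, exclude_cpg=True, cpg_opportunities=opp_cpg)
    total_full = sum(s.segregating for s in full.values())
    total_filt = sum(s.segregating for s in filtered.values())
    assert total_full - total_filt == 2  # exactly the flagged SNPs
    with pytest.raises(ValueError):
        build_sfs(snps, opp, Fmat, exclude_cpg=True)


def test_mixed_sample_sizes_rejected(hky):
    t = _snp_frame([("g", 0, "GAA", "GAT", 3, 16), ("g", 1, "GAA", "GAT", 2, 12)])
    snps = PolymorphismSet(t)
    exome = np.full(2, CODON_INDEX["GAA"])
    opp = mutational_opportunities(exome, hky, np.zeros((2, 20)))
    with pytest.raises(ValueError):
        build_sfs(snps, opp, np.zeros((2, 20)))


def test_classify_snps_reports_s0_and_class(rng):
    Fmat = rng.normal(0, 2, (1, 20))
    Fmat -= Fmat.mean(axis=1, keepdims=True)
    snps = PolymorphismSet(_snp_frame([("g", 0, "TCA", "CCA", 3, 16)]))
    out = classify_snps(snps, Fmat)
    expect = Fmat[0, AA_INDEX["P"]] - Fmat[0, AA_INDEX["S"]]
    assert out["S0"][0] == pytest.approx(expect)


# -- subsampling and diversity ------------------------------------------------

def _sfs(counts, n, L=1000.0, label="SYN"):
    return SiteFrequencySpectrum(counts=np.asarray(counts, float), n=n, L=L, label=label)


def test_subsample_identity_at_equal_size():
    s = _sfs(np.arange(1, 16), 16)
    assert subsample_sfs(s, 16) is s


def test_subsample_single_snp_closed_form():
    from scipy.stats import hypergeom

    n = 8
    s = _sfs([0, 0, 0, 1, 0, 0, 0], n)  # one SNP at i = 4
    out = subsample_sfs(s, 2)
    assert out.counts[0] == pytest.approx(hypergeom.pmf(1, n, 4, 2))


def test_sampling_variant_matches_exact_in_expectation():
    n, m = 16, 8
    counts = np.zeros(15)
    counts[4] = 10_000
    s = _sfs(counts, n)
    exact = subsample_sfs(s, m).counts
    sampled = subsample_sfs(s, m, method="sample", seed=3).counts
    se = np.sqrt(np.maximum(exact, 1.0))
    assert np.all(np.abs(sampled - exact) < 5 * se)


def test_subsample_size_bounds():
    s = _sfs(np.ones(15), 16)
    with pytest.raises(ValueError):
        subsample_sfs(s, 1)
    with pytest.raises(ValueError):
        subsample_sfs(s, 17)


def test_watterson_theta_pair_example():
    s = _sfs([5.0], 2, L=1000.0)
    assert watterson_theta(s) == pytest.approx(0.005)


def test_ne_from_theta_arithmetic():
    assert ne_estimate(4e-4, 1e-8) == pytest.approx(1e4)


def test_watterson_theta_unbiased_on_neutral_bundles():
    """theta_S over replicate neutral draws brackets the generative theta."""
    from mutselpop.dfe import PointMassDFE, expected_sfs

    theta, L, n = 0.01, 1e5, 16
    rng = np.random.default_rng(17)
    E = expected_sfs(PointMassDFE(S=0.0), theta, n, L)
    ests = []
    for _ in range(50):
        xi = rng.poisson(E).astype(float)
        ests.append(watterson_theta(_sfs(xi, n, L=L)))
    mean = float(np.mean(ests))
    se = float(np.std(ests, ddof=1) / np.sqrt(len(ests)))
    assert abs(mean - theta) < 3 * se + 1e-6
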