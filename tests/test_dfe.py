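"""DFE densities, PRF expectations, class probabilities and fitting."""
import numpy as np
import pytest
import scipy.integrate
from hypothesis import given, strategies as st

from mutselpop.dfe import (
    DFEModel,
    DiscreteDFE,
    PointMassDFE,
    class_probabilities,
    dfe_density,
    expected_divergence,
    expected_sfs,
    fit_dfe,
)
from mutselpop.prf import sojourn_grid, sojourn_sfs_weights

model_params = st.tuples(
    st.floats(-300.0, -1.0),   # beta_d
    st.floats(0.2, 5.0),       # b
    st.floats(0.0, 1.0),       # p_b
    st.floats(1.0, 50.0),      # beta_b
)


# -- sojourn weights ---------------------------------------------------------

def test_neutral_sojourn_weights_are_one_over_i():
    n = 16
    H = sojourn_sfs_weights(0.0, n)[0]
    np.testing.assert_allclose(H, 1.0 / np.arange(1, n), rtol=1e-10)


def test_sojourn_weights_match_adaptive_quadrature():
    n = 12
    for S in (-80.0, -3.0, 2.5, 40.0):
        H = sojourn_sfs_weights(S, n)[0]
        from scipy.special import comb

        for i in (1, 5, 11):
            val, _ = scipy.integrate.quad(
                lambda x: comb(n, i)
                * x**i
                * (1 - x) ** (n - i)
                * (1 - np.exp(-S * (1 - x)))
                / (x * (1 - x) * (1 - np.exp(-S))),
                0.0,
                1.0,
                limit=200,
            )
            assert H[i - 1] == pytest.approx(val, rel=1e-6)


def test_grid_interpolation_accurate_and_exact_at_zero():
    grid = sojourn_grid(16)
    S = np.array([0.0, 0.37, -12.3, 250.0])
    direct = sojourn_sfs_weights(S, 16)
    interp = grid.interp(S)
    np.testing.assert_allclose(interp[0], direct[0], rtol=1e-12)  # S=0 is a node
    np.testing.assert_allclose(interp, direct, rtol=5e-3)


# -- densities ---------------------------------------------------------------

def test_no_beneficial_mass_means_zero_density_above_zero():
    m = DFEModel(beta_d=-5.0, b=1.0, p_b=0.0, beta_b=2.0)
    assert np.all(dfe_density(m, np.linspace(0.1, 50, 25)) == 0.0)


def test_density_integrates_to_one(rng):
    for _ in range(5):
        m = DFEModel(
            beta_d=-float(rng.uniform(1, 200)),
            b=float(rng.uniform(0.2, 4)),
            p_b=float(rng.uniform(0, 1)),
            beta_b=float(rng.uniform(1, 30)),
        )
        neg, _ = scipy.integrate.quad(lambda s: dfe_density(m, s), -np.inf, 0, limit=300)
        pos, _ = scipy.integrate.quad(lambda s: dfe_density(m, s), 0, np.inf, limit=300)
        assert neg + pos == pytest.approx(1.0, abs=1e-6)


def test_shape_one_gamma_is_exponential():
    m = DFEModel(beta_d=-4.0, b=1.0, p_b=0.0, beta_b=2.0)
    s = np.linspace(-10, -0.1, 30)
    np.testing.assert_allclose(dfe_density(m, s), np.exp(s / 4.0) / 4.0, rtol=1e-10)


def test_out_of_bound_parameters_rejected():
    with pytest.raises(ValueError):
        DFEModel(beta_d=-0.5, b=1.0, p_b=0.1, beta_b=2.0)
    with pytest.raises(ValueError):
        DFEModel(beta_d=-5.0, b=0.1, p_b=0.1, beta_b=2.0)
    with pytest.raises(ValueError):
        DFEModel(beta_d=-5.0, b=1.0, p_b=0.1, beta_b=0.5)
    with pytest.raises(ValueError):
        DiscreteDFE(masses=np.array([0.5] * 7))


# -- class probabilities -----------------------------------------------------

def test_no_beneficial_mass_means_zero_beneficial_probability():
    m = DFEModel(beta_d=-5.0, b=1.0, p_b=0.0, beta_b=2.0)
    assert class_probabilities(m).p_ben == 0.0


def test_pure_exponential_beneficial_probability_is_exp_minus_one():
    m = DFEModel(beta_d=-5.0, b=1.0, p_b=1.0, beta_b=1.0)
    post = class_probabilities(m)
    assert post.p_ben == pytest.approx(np.exp(-1.0), rel=1e-12)
    # quadrature oracle for P[S > 1]
    val, _ = scipy.integrate.quad(lambda s: dfe_density(m, s), 1.0, np.inf, limit=200)
    assert post.p_ben == pytest.approx(val, rel=1e-8)


@given(model_params)
def test_class_probabilities_partition(params):
    beta_d, b, p_b, beta_b = params
    post = class_probabilities(DFEModel(beta_d, b, p_b, beta_b))
    arr = post.as_array()
    assert np.all(arr >= -1e-12)
    assert arr.sum() == pytest.approx(1.0, abs=1e-12)


def test_closed_form_deleterious_probability_matches_quadrature():
    m = DFEModel(beta_d=-8.0, b=0.6, p_b=0.2, beta_b=4.0)
    val, _ = scipy.integrate.quad(lambda s: dfe_density(m, s), -np.inf, -1.0, limit=300)
    assert class_probabilities(m).p_del == pytest.approx(val, rel=1e-7)


def test_discrete_class_probabilities_are_mass_sums():
    masses = np.array([0.05, 0.15, 0.2, 0.25, 0.2, 0.1, 0.05])
    post = class_probabilities(DiscreteDFE(masses=masses))
    assert post.p_del == pytest.approx(0.4)
    assert post.p_ben == pytest.approx(0.15)
    assert post.p_neutral == pytest.approx(0.45)


# -- expected SFS and divergence --------------------------------------------

def test_neutral_point_mass_expected_sfs_follows_one_over_i():
    E = expected_sfs(PointMassDFE(S=0.0), theta=1.0, n=4, L=100.0)
    np.testing.assert_allclose(E, [100.0, 50.0, 100.0 / 3.0], rtol=1e-10)


def test_half_mispolarization_symmetrizes_expected_sfs():
    m = DFEModel(beta_d=-10.0, b=0.5, p_b=0.1, beta_b=3.0, epsilon=0.5)
    E = expected_sfs(m, theta=0.01, n=16, L=1e5)
    np.testing.assert_allclose(E, E[::-1], rtol=1e-12)


def test_expected_divergence_point_masses():
    assert expected_divergence(PointMassDFE(S=0.0), 0.02, 1e4) == pytest.approx(200.0)
    assert expected_divergence(PointMassDFE(S=1.24), 0.02, 1e4) == pytest.approx(
        200.0 * 1.745, rel=5e-4
    )
    assert expected_divergence(PointMassDFE(S=-20.0), 0.02, 1e4) < 200.0 * 1e-7


def test_expected_sfs_matches_simulator_mean():
    """Poisson draws of the generator average to the fitter's forward model."""
    from mutselpop.mutsel import SiteFitnessProfile, profiles_to_matrix
    from mutselpop.mutation import NucleotideMutationModel
    from mutselpop.phylo import Phylogeny
    from mutselpop.synthetic import SimulationScenario, simulate_polymorphism

    n_sites, n = 300, 16
    mu = NucleotideMutationModel.hky(2.0, (0.3, 0.2, 0.2, 0.3))
    profiles = [SiteFitnessProfile(site=i, F=np.zeros(20)) for i in range(n_sites)]
    tree = Phylogeny.star(["focal"], 0.0)
    rng = np.random.default_rng(99)
    exome = rng.integers(0, 61, n_sites)
    total = np.zeros(n - 1)
    reps = 60
    sc = SimulationScenario(tree=tree, mu=mu, profiles=profiles, seed=0)
    theta_syn = 0.0
    for r in range(reps):
        sc2 = SimulationScenario(tree=tree, mu=mu, profiles=profiles, seed=r)
        _, sfs, _ = simulate_polymorphism(sc2, exome, mode="detail")
        total += sfs["SYN"].counts
    # total synonymous intensity of this exome (flat landscape -> neutral)
    from mutselpop.mutsel import change_tables

    ct = change_tables(exome, profiles_to_matrix(profiles), mu)
    theta_syn = sc.theta / mu.total_rate * float(ct["mu_weight"][ct["is_syn"]].sum())
    expected = expected_sfs(PointMassDFE(S=0.0), theta=theta_syn, n=n, L=1.0)
    mean = total / reps
    se = np.sqrt(expected / reps)
    assert np.all(np.abs(mean - expected) < 4.0 * se + 1e-9)


# -- fitting -----------------------------------------------------------------

def _poisson_data(model, theta, n, L_x, L_syn, seed):
    rng = np.random.default_rng(seed)
    E_x = expected_sfs(model, theta, n, L_x)
    E_syn = expected_sfs(PointMassDFE(S=0.0), theta, n, L_syn)
    return (rng.poisson(E_x).astype(float), n, L_x), (rng.poisson(E_syn).astype(float), n, L_syn)


def test_neutral_only_data_concentrates_mass_near_zero():
    # The discrete form can represent a near-neutral DFE exactly. (The
    # parametric mixture cannot: its component bounds beta_d <= -1 and
    # beta_b >= 1 cap P[N] at about 0.58 no matter the data.)
    neutral = PointMassDFE(S=0.0)
    sfs_x, sfs_syn = _poisson_data(neutral, 0.01, 16, 3e5, 3e5, seed=5)
    fit = fit_dfe(sfs_x, sfs_syn, form="discrete", seed=1)
    assert fit.class_posterior.p_neutral > 0.9


def test_all_zero_selected_sfs_flagged_degenerate():
    sfs_syn = (np.full(15, 10.0), 16, 1e4)
    sfs_x = (np.zeros(15), 16, 1e4)
    fit = fit_dfe(sfs_x, sfs_syn, form="parametric", seed=0)
    assert fit.degenerate
    assert fit.model.p_b == 0.0


def test_refit_on_fitted_expectations_is_self_consistent():
    true = DFEModel(beta_d=-30.0, b=0.5, p_b=0.1, beta_b=5.0)
    sfs_x, sfs_syn = _poisson_data(true, 0.01, 16, 1e6, 1e6, seed=7)
    fit1 = fit_dfe(sfs_x, sfs_syn, form="parametric", seed=3, n_starts=4)
    # replace the data by the fitted model's exact expectations and refit
    E_x = expected_sfs(fit1.model, fit1.theta, 16, 1e6)
    E_syn = expected_sfs(PointMassDFE(S=0.0), fit1.theta, 16, 1e6)
    fit2 = fit_dfe((E_x, 16, 1e6), (E_syn, 16, 1e6), form="parametric", seed=4, n_starts=4)
    p1, p2 = fit1.class_posterior.as_array(), fit2.class_posterior.as_array()
    np.testing.assert_allclose(p1, p2, atol=0.02)


def test_discrete_fit_agrees_with_parametric_on_parametric_data():
    true = DFEModel(beta_d=-30.0, b=0.5, p_b=0.1, beta_b=5.0)
    sfs_x, sfs_syn = _poisson_data(true, 0.01, 16, 1e6, 1e6, seed=11)
    fp = fit_dfe(sfs_x, sfs_syn, form="parametric", seed=2, n_starts=4)
    fd = fit_dfe(sfs_x, sfs_syn, form="discrete", seed=2, n_starts=4)
    # The binned form carries a discretization bias around the class
    # threshold at -1 (mass within a bin is spread on fixed nodes), so the
    # two forms agree to ~0.07 here rather than exactly.
    np.testing.assert_allclose(
        fp.class_posterior.as_array(), fd.class_posterior.as_array(), atol=0.1
    )


def test_likelihood_gauge_rescaling_absorbed_by_theta():
    true = DFEModel(beta_d=-20.0, b=0.8, p_b=0.05, beta_b=3.0)
    sfs_x, sfs_syn = _poisson_data(true, 0.01, 16, 5e5, 5e5, seed=13)
    fit1 = fit_dfe(sfs_x, sfs_syn, form="parametric", seed=6, n_starts=4)
    c = 10.0
    fit2 = fit_dfe(
        (sfs_x[0], 16, sfs_x[2] * c), (sfs_syn[0], 16, sfs_syn[2] * c),
        form="parametric", seed=6, n_starts=4,
    )
    assert fit2.theta == pytest.approx(fit1.theta / c, rel=1e-3)
    np.testing.assert_allclose(
        fit1.class_posterior.as_array(), fit2.class_posterior.as_array(), atol=0.02
    )


def test_mismatched_sample_sizes_rejected():
    with pytest.raises(ValueError):
        fit_dfe((np.ones(15), 16, 1e3), (np.ones(11), 12, 1e3))
    with pytest.raises(ValueError):
        fit_dfe((np.ones(15), 16, 1e3), (np.zeros(15), 16, 1e3))
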