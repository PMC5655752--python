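import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from dynloda import (
    MarkerSpec,
    MixtureParams,
    ModelConfig,
    PatientRecord,
    ValidationError,
    group_probs_one_draw,
    hpd_interval,
    marginal_loglik,
    marginal_loglik_gaussian,
    posterior_probabilities,
    slice_history,
    trajectory,
)
from dynloda.mglmm import GroupParams

from conftest import draws_from_params


def brute_force_hpd(samples, alpha):
    """Independent oracle: enumerate every contiguous sorted window."""
    s = np.sort(samples)
    m = max(1, min(int(np.ceil((1 - alpha) * s.size)), s.size))
    best = None
    for i in range(s.size - m + 1):
        w = s[i + m - 1] - s[i]
        if best is None or w < best[0] - 1e-12:
            best = (w, s[i], s[i + m - 1])
    return best[1], best[2]


# ---------------------------------------------------------------------------
# HPD intervals
# ---------------------------------------------------------------------------


def test_hpd_constant_samples_collapse():
    assert hpd_interval(np.full(40, 0.3), 0.05) == (0.3, 0.3)


@pytest.mark.parametrize("alpha, width", [(0.05, 0.94), (0.5, 0.49)])
def test_hpd_uniform_grid_window(alpha, width):
    grid = np.arange(0.01, 1.005, 0.01)
    low, upp = hpd_interval(grid, alpha)
    assert upp - low == pytest.approx(width, abs=1e-12)
    assert (low, upp) == pytest.approx(brute_force_hpd(grid, alpha), abs=1e-12)


@given(
    samples=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=60),
    alpha=st.sampled_from([0.01, 0.05, 0.1, 0.5, 0.9]),
)
@settings(deadline=None, max_examples=100)
def test_hpd_matches_enumeration(samples, alpha):
    got = hpd_interval(np.array(samples), alpha)
    assert got == pytest.approx(brute_force_hpd(samples, alpha), abs=1e-12)


def test_hpd_width_monotone_in_alpha():
    rng = np.random.default_rng(4)
    s = rng.beta(2, 5, size=300)
    widths = [np.diff(hpd_interval(s, a))[0] for a in (0.01, 0.05, 0.2, 0.5, 0.8)]
    assert np.all(np.diff(widths) <= 1e-12)


def test_hpd_parameter_validation():
    with pytest.raises(ValidationError):
        hpd_interval(np.array([0.5]), 0.0)
    with pytest.raises(ValidationError):
        hpd_interval(np.array([]), 0.1)


def test_hpd_equal_tail_fallback():
    s = np.arange(0.01, 1.005, 0.01)
    low, upp = hpd_interval(s, 0.1, method="equal_tail")
    assert low == pytest.approx(np.quantile(s, 0.05))
    assert upp == pytest.approx(np.quantile(s, 0.95))


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def single_marker_setup(family="gaussian", values=(0.2, 0.5), phi=0.5,
                        mean=0.4, var=0.3):
    marker = MarkerSpec("y", family)
    config = ModelConfig(markers=[marker], K=1, fixed_effects={"y": []})
    vals = np.asarray(values, dtype=float)
    patient = PatientRecord(
        "x", np.linspace(0.5, 2.0, vals.size), {"y": vals}, horizon=5.0
    )
    params = GroupParams(
        coefs={"y": np.array([0.1])},
        dispersions={"y": phi},
        mixture=MixtureParams(np.array([1.0]), np.array([[mean]]),
                              np.array([[[var]]])),
    )
    return config, patient, params


def test_marginal_loglik_empty_history_is_zero():
    config, patient, params = single_marker_setup()
    patient.observations["y"] = np.array([np.nan, np.nan])
    h = slice_history(patient, 2.0)
    assert marginal_loglik(h, params, config, n_mc=50) == 0.0
    assert marginal_loglik_gaussian(h, params, config) == 0.0


def test_marginal_loglik_gaussian_degenerate_covariance():
    """Near-zero random-effect variance: the marginal is the product of
    independent normal densities around X alpha + mu."""
    config, patient, params = single_marker_setup(var=1e-12, mean=0.0, phi=0.5)
    h = slice_history(patient, 2.0)
    direct = np.sum(
        -0.5 * (np.log(2 * np.pi * 0.5) + (patient.observations["y"] - 0.1) ** 2 / 0.5)
    )
    assert marginal_loglik_gaussian(h, params, config) == pytest.approx(direct, abs=1e-5)


def test_marginal_loglik_gaussian_degenerate_mixture():
    config, patient, params = single_marker_setup()
    two = GroupParams(
        coefs=params.coefs, dispersions=params.dispersions,
        mixture=MixtureParams(np.array([0.5, 0.5]), np.array([[0.4], [0.4]]),
                              np.array([[[0.3]], [[0.3]]])),
    )
    h = slice_history(patient, 2.0)
    assert marginal_loglik_gaussian(h, two, config) == pytest.approx(
        marginal_loglik_gaussian(h, params, config)
    )


def test_marginal_loglik_gaussian_rejects_other_families():
    config, patient, params = single_marker_setup(family="bernoulli",
                                                  values=(0.0, 1.0))
    with pytest.raises(ValidationError):
        marginal_loglik_gaussian(slice_history(patient, 2.0), params, config)


def test_mc_marginal_matches_gaussian_closed_form():
    config, patient, params = single_marker_setup()
    h = slice_history(patient, 2.0)
    exact = marginal_loglik_gaussian(h, params, config)
    est, se = marginal_loglik(h, params, config, n_mc=4000, seed=1, return_se=True)
    assert abs(est - exact) < 3 * se


def test_mc_marginal_matches_gauss_hermite_for_bernoulli():
    """Single binary observation, K=1 intercept model: compare the MC
    integral to 50-node Gauss-Hermite quadrature."""
    config, patient, params = single_marker_setup(
        family="bernoulli", values=(1.0,), mean=0.4, var=0.3
    )
    h = slice_history(patient, patient.times[-1])
    nodes, weights = np.polynomial.hermite_e.hermegauss(50)
    b = 0.4 + np.sqrt(0.3) * nodes
    quad = np.log(np.sum(weights * expit(0.1 + b)) / np.sqrt(2 * np.pi))
    est, se = marginal_loglik(h, params, config, n_mc=8000, seed=2, return_se=True)
    assert abs(est - quad) < 3 * se


# ---------------------------------------------------------------------------
# group probabilities
# ---------------------------------------------------------------------------


def test_group_probs_direct_arithmetic(monkeypatch):
    """log f = (-10, -12), priors (0.9, 0.1) -> P_1 = 0.014815..."""
    import dynloda.loda as loda_mod

    config, patient, params = single_marker_setup()
    h = slice_history(patient, 2.0)
    fakes = iter([-10.0, -12.0])
    monkeypatch.setattr(loda_mod, "marginal_loglik",
                        lambda *a, **k: next(fakes))
    p = group_probs_one_draw(h, [params, params], np.array([0.9, 0.1]), config,
                             n_mc=10)
    expected = 0.1 * np.exp(-12) / (0.9 * np.exp(-10) + 0.1 * np.exp(-12))
    assert p[1] == pytest.approx(expected, rel=1e-9)
    assert p[1] == pytest.approx(0.01481, abs=5e-6)


def test_group_probs_symmetry_and_prior_annihilation():
    config, patient, params = single_marker_setup()
    h = slice_history(patient, 2.0)
    p = group_probs_one_draw(h, [params, params], np.array([0.5, 0.5]), config)
    assert p == pytest.approx([0.5, 0.5])
    p = group_probs_one_draw(h, [params, params], np.array([1.0, 0.0]), config)
    assert p[1] == 0.0


def test_posterior_probabilities_constant_chain(fitted_small):
    dataset, draws = fitted_small
    # degenerate "chain": repeat one draw; all per-draw vectors must agree
    single = draws_from_params(draws.get(0), draws.config, M=4)
    p = dataset.patients[0]
    h = slice_history(p, p.times[-1])
    P, mean = posterior_probabilities(h, single, dataset.prevalences, n_mc=80,
                                      seed=3)
    assert np.allclose(P, P[0])
    np.testing.assert_allclose(mean, P[0])
    np.testing.assert_allclose(P.sum(axis=1), 1.0)


def test_vectorised_and_per_draw_paths_agree(fitted_small):
    """posterior_probabilities (vectorised over draws) must reproduce the
    per-draw Bayes computation with the same common random numbers."""
    from dynloda.loda import _base_draws

    dataset, draws = fitted_small
    p = dataset.patients[3]
    h = slice_history(p, p.times[-1])
    base = _base_draws(3, p.patient_id, 0, 80, draws.config.q)
    P, _ = posterior_probabilities(h, draws, dataset.prevalences, n_mc=80,
                                   seed=3)
    ref = np.stack([
        group_probs_one_draw(h, draws.get(m), dataset.prevalences,
                             draws.config, base=base)
        for m in range(draws.M)
    ])
    np.testing.assert_allclose(P, ref, atol=1e-12)


def test_empty_history_returns_prior(fitted_small):
    dataset, draws = fitted_small
    p = dataset.patients[0]
    blank = PatientRecord(
        "blank", p.times[:2],
        {m.name: np.full(2, np.nan) for m in dataset.markers},
        covariates=p.covariates and {k: v[:2] for k, v in p.covariates.items()},
        horizon=p.horizon,
    )
    h = slice_history(blank, blank.times[-1])
    P, mean = posterior_probabilities(h, draws, dataset.prevalences, n_mc=40)
    np.testing.assert_allclose(mean, dataset.prevalences)
    np.testing.assert_allclose(P, np.tile(dataset.prevalences, (draws.M, 1)))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def test_trajectory_shapes_and_normalisation(fitted_small):
    dataset, draws = fitted_small
    p = next(q for q in dataset.patients if q.n_visits >= 3)
    tr = trajectory(p, draws, dataset.prevalences, alpha=0.05, n_mc=60, seed=9)
    assert tr.times.size == p.n_visits
    np.testing.assert_allclose(tr.p_draws.sum(axis=2), 1.0, atol=1e-12)
    np.testing.assert_allclose(tr.means, tr.p_draws.mean(axis=1))
    assert np.all(tr.low <= tr.upp) and np.all(tr.low >= 0) and np.all(tr.upp <= 1)


def test_trajectory_single_visit(fitted_small):
    dataset, draws = fitted_small
    p = dataset.patients[0]
    solo = PatientRecord(
        "solo", p.times[:1],
        {m.name: p.observations[m.name][:1] for m in dataset.markers},
        covariates={k: v[:1] for k, v in p.covariates.items()},
        horizon=p.horizon,
    )
    tr = trajectory(solo, draws, dataset.prevalences, n_mc=40, seed=1)
    assert tr.times.size == 1


def test_trajectory_hpd_width_monotone_in_alpha(fitted_small):
    dataset, draws = fitted_small
    p = next(q for q in dataset.patients if q.n_visits >= 3)
    wide = trajectory(p, draws, dataset.prevalences, alpha=0.01, n_mc=60, seed=9)
    narrow = trajectory(p, draws, dataset.prevalences, alpha=0.5, n_mc=60, seed=9)
    assert np.all((wide.upp - wide.low) >= (narrow.upp - narrow.low) - 1e-12)


def test_separated_patient_gets_extreme_probability(sim_small):
    """A patient deep in disease territory must get P_1 > 0.99 under the
    true parameters."""
    cfg, dataset, _ = sim_small
    truth_draws = draws_from_params(cfg.group_params, cfg.model_config(), M=3)
    times = np.linspace(0.3, 4.5, 8)
    disease = PatientRecord(
        "deep", times,
        {
            "seizure": np.ones(8),
            "log_seizures": np.full(8, 2.2),
            "adverse_events": np.full(8, 3.0),
        },
        horizon=5.0,
    )
    tr = trajectory(disease, truth_draws, cfg.prevalences, n_mc=200, seed=5)
    assert tr.means[-1, 1] > 0.99
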