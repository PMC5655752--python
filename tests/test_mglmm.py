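import numpy as np
import pytest
from scipy.stats import multivariate_normal

from dynloda import (
    Dataset,
    MarkerSpec,
    MixtureParams,
    ModelConfig,
    PatientRecord,
    ValidationError,
    build_design,
    fit_mglmm,
    load_draws,
    mixture_logpdf,
    obs_loglik,
    save_draws,
)
from dynloda.core_data import slice_history
from dynloda.simulate import SimConfig, simulate_dataset
from dynloda.mglmm import GroupParams


# ---------------------------------------------------------------------------
# observation log-likelihood
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "y, eta, family, phi, expected",
    [
        (0.7, 0.7, "gaussian", 1.0, -0.5 * np.log(2 * np.pi)),
        (1.0, 50.0, "bernoulli", 1.0, 0.0),  # saturation limit
        (3.0, np.log(2.0), "poisson", 1.0, 3 * np.log(2) - 2 - np.log(6)),
    ],
)
def test_obs_loglik_values(y, eta, family, phi, expected):
    assert obs_loglik(y, eta, family, phi) == pytest.approx(expected, abs=1e-9)


def test_obs_loglik_rejects_nonpositive_dispersion():
    with pytest.raises(ValidationError):
        obs_loglik(0.0, 0.0, "gaussian", phi=0.0)


# ---------------------------------------------------------------------------
# mixture density
# ---------------------------------------------------------------------------


def test_mixture_logpdf_standard_normal_mode():
    mix = MixtureParams(np.array([1.0]), np.zeros((1, 3)), np.eye(3)[None])
    assert mixture_logpdf(np.zeros(3), mix) == pytest.approx(-1.5 * np.log(2 * np.pi))


def test_mixture_degenerate_two_components_equal_one():
    mu, D = np.array([0.4, -0.2]), np.array([[0.5, 0.1], [0.1, 0.3]])
    one = MixtureParams(np.array([1.0]), mu[None], D[None])
    two = MixtureParams(np.array([0.5, 0.5]), np.stack([mu, mu]), np.stack([D, D]))
    b = np.array([0.3, 0.1])
    assert mixture_logpdf(b, two) == pytest.approx(mixture_logpdf(b, one))


def test_mixture_logpdf_matches_naive_sum():
    w = np.array([0.3, 0.7])
    mus = np.array([[0.0, 1.0], [-1.0, 0.5]])
    covs = np.stack([np.array([[1.0, 0.2], [0.2, 0.8]]), np.eye(2) * 0.5])
    mix = MixtureParams(w, mus, covs)
    b = np.array([0.2, 0.4])
    naive = np.log(
        sum(w[k] * multivariate_normal.pdf(b, mus[k], covs[k]) for k in range(2))
    )
    assert mixture_logpdf(b, mix) == pytest.approx(naive, rel=1e-10)


def test_mixture_label_switching_invariance():
    w = np.array([0.3, 0.7])
    mus = np.array([[0.0, 1.0], [-1.0, 0.5]])
    covs = np.stack([np.eye(2), np.eye(2) * 0.5])
    b = np.array([-0.3, 0.9])
    a = mixture_logpdf(b, MixtureParams(w, mus, covs))
    p = mixture_logpdf(b, MixtureParams(w[::-1], mus[::-1], covs[::-1]))
    assert a == pytest.approx(p, rel=1e-12)


def test_mixture_density_integrates_to_one_2d():
    mix = MixtureParams(
        np.array([0.4, 0.6]),
        np.array([[0.5, -0.5], [-0.5, 0.5]]),
        np.stack([np.eye(2) * 0.4, np.array([[0.6, 0.2], [0.2, 0.5]])]),
    )
    grid = np.linspace(-6, 6, 241)
    xx, yy = np.meshgrid(grid, grid)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    dens = np.exp(mixture_logpdf(pts, mix)).reshape(xx.shape)
    integral = np.trapezoid(np.trapezoid(dens, grid, axis=1), grid)
    assert integral == pytest.approx(1.0, abs=1e-4)


def test_mixture_dimension_mismatch():
    mix = MixtureParams(np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None])
    with pytest.raises(ValidationError):
        mixture_logpdf(np.zeros(3), mix)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def three_marker_patient():
    return PatientRecord(
        patient_id="d",
        times=np.array([0.5, 1.0, 2.0]),
        observations={
            "a": np.array([1.0, 0.0, 1.0]),
            "b": np.array([0.2, np.nan, 0.4]),
            "c": np.array([2.0, 1.0, 0.0]),
        },
        covariates={"age": np.array([40.0, 40.0, 40.0])},
    )


def test_build_design_intercept_only():
    config = ModelConfig(markers=[MarkerSpec("a", "bernoulli"),
                                  MarkerSpec("b", "gaussian"),
                                  MarkerSpec("c", "poisson")])
    h = slice_history(three_marker_patient(), 2.0)
    design = build_design(h, config)
    y, X, r = design["a"]
    assert X.shape == (3, 1) and np.all(X == 1.0) and r == 0
    # missing marker value contributes no row
    yb, Xb, rb = design["b"]
    assert yb.size == 2 and rb == 1
    assert design["c"][2] == 2  # unit basis position per marker


def test_build_design_covariate_order_and_unknown_name():
    config = ModelConfig(
        markers=[MarkerSpec("a", "bernoulli")],
        fixed_effects={"a": ["age", "time"]},
    )
    h = slice_history(three_marker_patient(), 1.0)
    _, X, _ = build_design(h, config)["a"]
    np.testing.assert_array_equal(X, [[1.0, 40.0, 0.5], [1.0, 40.0, 1.0]])
    bad = ModelConfig(markers=[MarkerSpec("a", "bernoulli")],
                      fixed_effects={"a": ["bmi"]})
    with pytest.raises(ValidationError, match="bmi"):
        build_design(h, bad)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def gaussian_only_config(n, seed, slope0=-0.3, slope1=0.2, mu0=1.3, mu1=1.8):
    """One gaussian marker, K=1: slopes in alpha, intercepts in the
    mixture means (the identifiable parameterisation)."""
    marker = MarkerSpec("y", "gaussian")
    def gp(slope, mean, phi):
        return GroupParams(
            coefs={"y": np.array([slope])},
            dispersions={"y": phi},
            mixture=MixtureParams(np.array([1.0]), np.array([[mean]]),
                                  np.array([[[0.4]]])),
        )
    return SimConfig(
        n_patients=n,
        prevalences=np.array([0.5, 0.5]),
        markers=[marker],
        group_params=[gp(slope0, mu0, 0.5), gp(slope1, mu1, 0.5)],
        fixed_effects={"y": ["time"]},
        seed=seed,
    )


def test_fit_is_deterministic_under_seed(sim_small):
    cfg, dataset, _ = sim_small
    sub = Dataset(dataset.patients[:30], dataset.markers, 2, dataset.prevalences)
    a = fit_mglmm(sub, cfg.model_config(), n_iter=60, n_burn=30, seed=5)
    b = fit_mglmm(sub, cfg.model_config(), n_iter=60, n_burn=30, seed=5)
    for ga, gb in zip(a.groups, b.groups):
        np.testing.assert_array_equal(ga.weights, gb.weights)
        for name in ga.alpha:
            np.testing.assert_array_equal(ga.alpha[name], gb.alpha[name])


def test_fit_requires_all_groups_and_labels(sim_small):
    cfg, dataset, _ = sim_small
    only0 = Dataset(
        [p for p in dataset.patients if p.true_group == 0][:10],
        dataset.markers, 2, dataset.prevalences,
    )
    with pytest.raises(ValidationError, match="group 1"):
        fit_mglmm(only0, cfg.model_config(), n_iter=20, n_burn=10)


def test_gaussian_k1_posterior_matches_gls():
    """With one gaussian marker and K=1 the model is a linear mixed model;
    the posterior mean of alpha must agree with the GLS estimate computed
    from the true variance components."""
    cfg = gaussian_only_config(240, seed=3)
    dataset, _ = simulate_dataset(cfg)
    draws = fit_mglmm(dataset, cfg.model_config(), n_iter=800, n_burn=400,
                      thin=4, seed=9)
    for g in range(2):
        gp = cfg.group_params[g]
        tau2, phi = gp.mixture.covs[0, 0, 0], gp.dispersions["y"]
        A = np.zeros((2, 2))
        v = np.zeros(2)
        for p in dataset.patients:
            if p.true_group != g:
                continue
            X = np.column_stack([p.times, np.ones(p.n_visits)])  # (slope, mu)
            V = tau2 + phi * np.eye(p.n_visits)
            Vi = np.linalg.inv(V)
            A += X.T @ Vi @ X
            v += X.T @ Vi @ p.observations["y"]
        gls = np.linalg.solve(A, v)
        post = np.array([
            draws.groups[g].alpha["y"][:, 0].mean(),
            draws.groups[g].means[:, 0, 0].mean(),
        ])
        sd = np.array([
            draws.groups[g].alpha["y"][:, 0].std(),
            draws.groups[g].means[:, 0, 0].std(),
        ])
        assert np.all(np.abs(post - gls) < 4 * np.maximum(sd, 0.02))


def test_separation_stress_all_zero_bernoulli_stays_finite():
    rng = np.random.default_rng(0)
    marker = MarkerSpec("z", "bernoulli")
    patients = []
    for i in range(30):
        times = np.sort(rng.uniform(0.1, 4.5, size=4))
        y = np.zeros(4) if i < 15 else rng.binomial(1, 0.6, size=4).astype(float)
        patients.append(PatientRecord(f"s{i}", times, {"z": y},
                                      true_group=int(i >= 15)))
    ds = Dataset(patients, [marker], 2, np.array([0.5, 0.5]))
    config = ModelConfig(markers=[marker], K=1)
    draws = fit_mglmm(ds, config, n_iter=200, n_burn=100, seed=2)
    a0 = draws.groups[0].alpha["z"][:, 0]
    assert np.all(np.isfinite(a0)) and np.all(np.isfinite(draws.groups[0].means))
    # the identified intercept (fixed + random-intercept mean) is strongly negative
    assert (a0 + draws.groups[0].means[:, 0, 0]).mean() < -1.0


def test_acceptance_rates_reported_in_adapted_range(fitted_small):
    _, draws = fitted_small
    for g in range(2):
        diag = draws.diagnostics[f"group{g}"]
        assert 0.1 <= diag["accept_b"] <= 0.9


def test_save_load_round_trip(tmp_path, fitted_small):
    _, draws = fitted_small
    path = tmp_path / "draws.npz"
    save_draws(draws, path)
    back = load_draws(path)
    assert back.M == draws.M and back.seed == draws.seed
    for ga, gb in zip(draws.groups, back.groups):
        np.testing.assert_array_equal(ga.covs, gb.covs)
        for name in ga.alpha:
            np.testing.assert_array_equal(ga.alpha[name], gb.alpha[name])
    assert back.config.to_dict() == draws.config.to_dict()
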