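import numpy as np
import pytest

from dynloda import (
    GroupParams,
    ModelConfig,
    PosteriorDraws,
    default_sanad_like_config,
    fit_mglmm,
    simulate_dataset,
)
from dynloda.loda import ProbabilityTrajectory
from dynloda.mglmm import GroupDraws


def draws_from_params(group_params: list[GroupParams], config: ModelConfig,
                      M: int = 5) -> PosteriorDraws:
    """A degenerate 'posterior' repeating fixed parameters M times.

    Lets trajectory/rule machinery run under known true parameters.
    """
    groups = []
    for gp in group_params:
        groups.append(
            GroupDraws(
                alpha={k: np.tile(v, (M, 1)) for k, v in gp.coefs.items()},
                phi={k: np.full(M, v) for k, v in gp.dispersions.items()},
                weights=np.tile(gp.mixture.weights, (M, 1)),
                means=np.tile(gp.mixture.means, (M, 1, 1)),
                covs=np.tile(gp.mixture.covs, (M, 1, 1, 1)),
            )
        )
    return PosteriorDraws(groups=groups, config=config, seed=0)


def make_traj(p_disease, low=None, upp=None, times=None, horizon=5.0,
              patient_id="T", true_group=None, alpha=0.05):
    """Build a two-group trajectory from stated disease probabilities."""
    p = np.asarray(p_disease, dtype=float)
    n = p.size
    times = np.asarray(times if times is not None else np.arange(1, n + 1),
                       dtype=float)
    low = p.copy() if low is None else np.asarray(low, dtype=float)
    upp = p.copy() if upp is None else np.asarray(upp, dtype=float)
    means = np.column_stack([1 - p, p])
    p_draws = np.repeat(means[:, None, :], 3, axis=1)
    return ProbabilityTrajectory(
        patient_id=patient_id, times=times, p_draws=p_draws, means=means,
        low=np.column_stack([1 - upp, low]), upp=np.column_stack([1 - low, upp]),
        alpha=alpha, horizon=horizon, true_group=true_group,
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small mixed-marker dataset with ground truth."""
    cfg = default_sanad_like_config(80, seed=11)
    dataset, truth = simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """A short but usable MCMC fit of the small dataset."""
    cfg, dataset, _ = sim_small
    draws = fit_mglmm(dataset, cfg.model_config(), n_iter=300, n_burn=150,
                      thin=3, seed=7)
    return dataset, draws
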