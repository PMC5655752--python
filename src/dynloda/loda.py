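"""Marginal group-membership probabilities and their posterior spread.

Given fitted group-specific MGLMMs, the marginal density of a patient's
marker history in group ``g`` integrates the observation likelihood over
the random-effect mixture:

    f_g(y) = ∫ Π_r Π_j p_r(y_rj | b) · Σ_k w_k N(b; mu_k, D_k) db .

Bayes' theorem combines these densities with the group prevalences
π_g into membership probabilities P_g(t).  Evaluated at every draw of an
MCMC sample from the posterior of the model parameters, P_g(t) acquires
its own posterior distribution; its mean is the point estimate used by
classical allocation rules, and its highest-posterior-density (HPD)
interval quantifies how certain that point estimate is — the ingredient
the credible-interval allocation rule consumes.

The integral is estimated by plain Monte Carlo from the mixture, with
common random numbers shared across groups within a draw to reduce the
variance of the density ratio.  When every marker is gaussian the
marginal is itself a normal mixture and an exact closed form is
available (:func:`marginal_loglik_gaussian`), used as a cross-check of
the Monte-Carlo path.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_data import HistorySlice, PatientRecord, ValidationError, slice_history
from .mglmm import (
    GroupParams,
    ModelConfig,
    PosteriorDraws,
    build_design,
    obs_loglik,
)

__all__ = [
    "ProbabilityTrajectory",
    "marginal_loglik",
    "marginal_loglik_gaussian",
    "group_probs_one_draw",
    "posterior_probabilities",
    "hpd_interval",
    "trajectory",
    "export_trajectories",
]


@dataclass
class ProbabilityTrajectory:
    """Per-visit posterior distribution of the group probabilities.

    ``p_draws[j, m, g]`` is P_g at visit ``j`` under posterior draw
    ``m``; ``means`` averages over draws; ``low``/``upp`` are the
    per-group (1-alpha) HPD bounds of the per-draw probabilities.
    """

    patient_id: str
    times: np.ndarray  # (n,)
    p_draws: np.ndarray  # (n, M, G)
    means: np.ndarray  # (n, G)
    low: np.ndarray  # (n, G)
    upp: np.ndarray  # (n, G)
    alpha: float
    horizon: float
    true_group: int | None = None

    def __post_init__(self):
        if not np.all((self.low <= self.upp + 1e-12)):
            raise ValidationError("HPD lower bound above upper bound")

    @property
    def M(self) -> int:
        return int(self.p_draws.shape[1])

    def disease(self, group: int = 1):
        """(means, low, upp) for the disease group."""
        return self.means[:, group], self.low[:, group], self.upp[:, group]


# ---------------------------------------------------------------------------
# Monte-Carlo base draws (common random numbers)
# ---------------------------------------------------------------------------


def _patient_entropy(patient_id: str) -> int:
    return zlib.crc32(patient_id.encode())


def _base_draws(seed: int, patient_id: str, visit_index: int, n_mc: int, q: int):
    """Reproducible, patient-order-independent MC base variates.

    One block per (seed, patient, visit), shared by every posterior draw
    and every group: with identical parameters in two draws the
    resulting probabilities are identical, so the spread of the per-draw
    probabilities reflects parameter uncertainty, not integration noise.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(_patient_entropy(patient_id), visit_index))
    rng = np.random.default_rng(ss)
    E = rng.standard_normal((n_mc, q))
    U = rng.random(n_mc)
    return E, U


def _mixture_samples(mix, E: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Map base variates through the mixture: component by inverse-CDF on
    the weights, location/scale by the component Cholesky factors."""
    cum = np.cumsum(mix.weights)
    comp = np.minimum(np.searchsorted(cum, U, side="right"), mix.K - 1)
    b = np.empty_like(E)
    for k in range(mix.K):
        idx = comp == k
        if np.any(idx):
            L = np.linalg.cholesky(mix.covs[k])
            b[idx] = mix.means[k] + E[idx] @ L.T
    return b


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def _design_loglik(design, params: GroupParams, config: ModelConfig, b: np.ndarray):
    """Observation log-likelihood for each random-effect sample (rows of b)."""
    ll = np.zeros(b.shape[0])
    for m in config.markers:
        y, X, r = design[m.name]
        if y.size == 0:
            continue
        eta = (X @ params.coefs[m.name])[None, :] + b[:, [r]]
        ll += obs_loglik(y[None, :], eta, m.family, params.dispersions[m.name]).sum(axis=1)
    return ll


def marginal_loglik(history: HistorySlice, params: GroupParams, config: ModelConfig,
                    n_mc: int = 200, seed: int | None = 0,
                    base: tuple[np.ndarray, np.ndarray] | None = None,
                    return_se: bool = False):
    """Monte-Carlo estimate of the log marginal density of ``history``.

    Draws ``n_mc`` random-effect vectors from the mixture, averages the
    exponentiated observation log-likelihood, and returns a stable log
    of that average.  An empty history (no observed marker values)
    returns 0 — the empty product integrates to 1.  With
    ``return_se=True`` also returns the delta-method standard error of
    the log estimate.
    """
    if n_mc < 1:
        raise ValidationError("n_mc must be >= 1")
    design = build_design(history, config)
    n_obs = sum(design[m.name][0].size for m in config.markers)
    if n_obs == 0:
        return (0.0, 0.0) if return_se else 0.0
    if base is None:
        rng = np.random.default_rng(seed)
        E = rng.standard_normal((n_mc, config.q))
        U = rng.random(n_mc)
    else:
        E, U = base
    b = _mixture_samples(params.mixture, E, U)
    ll = _design_loglik(design, params, config, b)
    log_mean = logsumexp(ll) - np.log(ll.size)
    if not return_se:
        return float(log_mean)
    w = np.exp(ll - log_mean)  # mean(w) == 1
    se = float(np.std(w) / np.sqrt(ll.size))
    return float(log_mean), se


def marginal_loglik_gaussian(history: HistorySlice, params: GroupParams,
                             config: ModelConfig) -> float:
    """Exact log marginal density when every marker is gaussian.

    The marginal of the stacked observation vector is a K-component
    normal mixture N(X alpha, Z D_k Z' + Phi).
    """
    for m in config.markers:
        if m.family != "gaussian":
            raise ValidationError("marginal_loglik_gaussian requires all-gaussian markers")
    design = build_design(history, config)
    ys, mus, zcols, phis = [], [], [], []
    for m in config.markers:
        y, X, r = design[m.name]
        ys.append(y)
        mus.append(X @ params.coefs[m.name])
        zcols.append(np.full(y.size, r))
        phis.append(np.full(y.size, params.dispersions[m.name]))
    y = np.concatenate(ys)
    if y.size == 0:
        return 0.0
    mu = np.concatenate(mus)
    Z = np.zeros((y.size, config.q))
    Z[np.arange(y.size), np.concatenate(zcols).astype(int)] = 1.0
    Phi = np.diag(np.concatenate(phis))
    mix = params.mixture
    parts = []
    for k in range(mix.K):
        cov = Z @ mix.covs[k] @ Z.T + Phi
        mean = mu + Z @ mix.means[k]
        L = np.linalg.cholesky(cov)
        u = np.linalg.solve(L, y - mean)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        lp = -0.5 * (y.size * np.log(2 * np.pi) + logdet + u @ u)
        parts.append(np.log(mix.weights[k]) + lp)
    return float(logsumexp(parts))


# ---------------------------------------------------------------------------
# group probabilities
# ---------------------------------------------------------------------------


def group_probs_one_draw(history: HistorySlice, draw_params: list[GroupParams],
                         prevalences: np.ndarray, config: ModelConfig,
                         n_mc: int = 200, seed: int | None = 0,
                         base: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Bayes posterior membership probabilities under one parameter draw.

    The same Monte-Carlo base variates are used for every group (common
    random numbers), so the density ratio is estimated with lower
    variance than with independent streams.
    """
    prevalences = np.asarray(prevalences, dtype=float)
    if not np.isclose(prevalences.sum(), 1.0) or np.any(prevalences < 0):
        raise ValidationError("prevalences must form a simplex")
    if base is None:
        rng = np.random.default_rng(seed)
        base = (rng.standard_normal((n_mc, config.q)), rng.random(n_mc))
    logf = np.array(
        [
            marginal_loglik(history, gp, config, n_mc=n_mc, base=base)
            for gp in draw_params
        ]
    )
    with np.errstate(divide="ignore"):
        lognum = np.log(prevalences) + logf
    if np.all(np.isinf(lognum) & (lognum < 0)):
        raise ValidationError("all group densities underflow: degenerate evidence")
    return np.exp(lognum - logsumexp(lognum))


def _logf_all_draws(design, gd, config: ModelConfig,
                    E: np.ndarray, U: np.ndarray) -> np.ndarray:
    """log marginal density under every stored draw at once.

    ``E`` (S, q) and ``U`` (S,) are the common base variates shared by
    all draws.  Vectorised equivalent of calling
    :func:`marginal_loglik` per draw with the same base.
    """
    S, q = E.shape
    M = gd.weights.shape[0]
    K = gd.weights.shape[1]
    cum = np.cumsum(gd.weights, axis=1)  # (M, K)
    comp = np.minimum((U[None, :, None] >= cum[:, None, :]).sum(axis=2), K - 1)
    L = np.linalg.cholesky(gd.covs)  # (M, K, q, q)
    rows = np.arange(M)[:, None]
    b = gd.means[rows, comp] + np.einsum("msij,sj->msi", L[rows, comp], E)
    ll = np.zeros((M, S))
    for mk in config.markers:
        y, X, r = design[mk.name]
        if y.size == 0:
            continue
        A = gd.alpha[mk.name] @ X.T  # (M, n_obs)
        eta = A[:, None, :] + b[:, :, r : r + 1]
        phi = gd.phi[mk.name][:, None, None] if mk.family == "gaussian" else 1.0
        ll += obs_loglik(y[None, None, :], eta, mk.family, phi).sum(axis=2)
    return logsumexp(ll, axis=1) - np.log(S)


def posterior_probabilities(history: HistorySlice, draws: PosteriorDraws,
                            prevalences: np.ndarray, n_mc: int = 200,
                            seed: int = 0, visit_index: int = 0,
                            base: tuple[np.ndarray, np.ndarray] | None = None):
    """Per-draw membership probabilities and their posterior mean.

    Returns ``(P, P_mean)`` with ``P`` of shape (M, G).  The model is
    never refitted: each stored draw's parameters are simply reused,
    with the Monte-Carlo base variates shared across groups.
    """
    M, G = draws.M, draws.G
    prevalences = np.asarray(prevalences, dtype=float)
    if base is None:
        base = _base_draws(seed, history.patient.patient_id, visit_index,
                           n_mc, draws.config.q)
    E, U = base
    design = build_design(history, draws.config)
    n_obs = sum(design[m.name][0].size for m in draws.config.markers)
    if n_obs == 0:
        P = np.tile(prevalences, (M, 1))
        return P, P.mean(axis=0)
    logf = np.stack(
        [_logf_all_draws(design, gd, draws.config, E, U) for gd in draws.groups],
        axis=1,
    )  # (M, G)
    with np.errstate(divide="ignore"):
        lognum = np.log(prevalences)[None, :] + logf
    bad = np.all(np.isneginf(lognum), axis=1)
    if np.any(bad):
        raise ValidationError("all group densities underflow: degenerate evidence")
    P = np.exp(lognum - logsumexp(lognum, axis=1, keepdims=True))
    return P, P.mean(axis=0)


# ---------------------------------------------------------------------------
# HPD intervals and trajectories
# ---------------------------------------------------------------------------


def hpd_interval(samples: np.ndarray, alpha: float,
                 method: str = "hpd") -> tuple[float, float]:
    """Empirical shortest interval containing ceil((1-alpha) M) samples.

    Sliding-window minimisation over the sorted sample; ties broken by
    the smallest lower endpoint.  ``method="equal_tail"`` falls back to
    the (alpha/2, 1-alpha/2) quantile interval for use when the
    posterior may be multimodal.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float))
    if s.size == 0:
        raise ValidationError("empty sample")
    if method == "equal_tail":
        return (
            float(np.quantile(s, alpha / 2)),
            float(np.quantile(s, 1 - alpha / 2)),
        )
    m = int(np.ceil((1 - alpha) * s.size))
    m = max(1, min(m, s.size))
    if m == s.size:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: s.size - m + 1]
    # first window within float tolerance of the minimum: ties resolve to
    # the smallest lower endpoint
    i = int(np.argmax(widths <= widths.min() + 1e-12))
    return float(s[i]), float(s[i + m - 1])


def trajectory(patient: PatientRecord, draws: PosteriorDraws,
               prevalences: np.ndarray, alpha: float = 0.01,
               n_mc: int = 200, seed: int = 0,
               hpd_method: str = "hpd") -> ProbabilityTrajectory:
    """Membership probabilities, means and HPD bounds at every visit."""
    n, M, G = patient.n_visits, draws.M, draws.G
    p_draws = np.empty((n, M, G))
    for j in range(n):
        h = slice_history(patient, patient.times[j])
        P, _ = posterior_probabilities(
            h, draws, prevalences, n_mc=n_mc, seed=seed, visit_index=j
        )
        p_draws[j] = P
    means = p_draws.mean(axis=1)
    low = np.empty((n, G))
    upp = np.empty((n, G))
    for j in range(n):
        for g in range(G):
            low[j, g], upp[j, g] = hpd_interval(p_draws[j, :, g], alpha, hpd_method)
    return ProbabilityTrajectory(
        patient_id=patient.patient_id,
        times=patient.times.copy(),
        p_draws=p_draws,
        means=means,
        low=low,
        upp=upp,
        alpha=alpha,
        horizon=patient.horizon,
        true_group=patient.true_group,
    )


def export_trajectories(trajs: list[ProbabilityTrajectory], path) -> pd.DataFrame:
    """Tidy CSV: one row per (patient, time, group)."""
    rows = []
    for tr in trajs:
        for j, t in enumerate(tr.times):
            for g in range(tr.means.shape[1]):
                rows.append(
                    {
                        "patient_id": tr.patient_id,
                        "time": t,
                        "group": g,
                        "p_mean": tr.means[j, g],
                        "p_low": tr.low[j, g],
                        "p_upp": tr.upp[j, g],
                        "alpha": tr.alpha,
                        "M": tr.M,
                    }
                )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
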