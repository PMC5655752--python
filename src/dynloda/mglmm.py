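"""Group-specific multivariate generalised linear mixed model (MGLMM).

For each prognostic group ``g`` the ``R`` longitudinal markers of a
patient are modelled jointly: marker ``r`` follows an exponential-family
distribution (gaussian, bernoulli or poisson, canonical link) with
linear predictor

    h_r^{-1}( E[Y_rj | b] ) = x_rj' alpha_rg + b_r ,

where ``b = (b_1, ..., b_R)`` is a vector of correlated per-marker
random intercepts.  Robustness to distributional misspecification comes
from giving ``b`` a K-component multivariate normal mixture distribution
with group-specific weights, means and covariances.

Fitting is Bayesian, by a Metropolis-within-Gibbs sampler: conjugate
updates for gaussian regression coefficients and residual variances and
for the mixture parameters given component allocations, adaptive
random-walk Metropolis for the random effects and for the coefficients
of non-gaussian markers.  Groups are fitted independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import invwishart

from .core_data import Dataset, HistorySlice, MarkerSpec, ValidationError

__all__ = [
    "MixtureParams",
    "GroupParams",
    "GroupDraws",
    "PosteriorDraws",
    "ModelConfig",
    "Priors",
    "build_design",
    "obs_loglik",
    "mixture_logpdf",
    "fit_mglmm",
    "save_draws",
    "load_draws",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class MixtureParams:
    """K-component multivariate normal mixture for the random effects."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, q)
    covs: np.ndarray  # (K, q, q)

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim == 2:
            self.covs = self.covs[None, :, :]
        K = self.weights.size
        if not np.isclose(self.weights.sum(), 1.0) or np.any(self.weights <= 0):
            raise ValidationError("mixture weights must be a strictly positive simplex")
        if self.means.shape[0] != K or self.covs.shape[0] != K:
            raise ValidationError("mixture component count mismatch")
        for k in range(K):
            try:
                np.linalg.cholesky(self.covs[k])
            except np.linalg.LinAlgError as e:
                raise ValidationError(f"mixture covariance {k} not positive definite") from e

    @property
    def K(self) -> int:
        return int(self.weights.size)

    @property
    def dim(self) -> int:
        return int(self.means.shape[1])


@dataclass
class GroupParams:
    """All parameters of one group's MGLMM: (psi, theta)."""

    coefs: dict[str, np.ndarray]  # marker -> regression coefficients
    dispersions: dict[str, float]  # marker -> phi (1.0 for non-gaussian)
    mixture: MixtureParams

    def __post_init__(self):
        for name, phi in self.dispersions.items():
            if not phi > 0:
                raise ValidationError(f"dispersion for marker {name!r} must be > 0")


@dataclass
class ModelConfig:
    """Model structure shared by fitting and prediction.

    ``fixed_effects`` lists covariate names per marker (the special name
    ``"time"`` refers to the visit time).  The random-effect structure
    is a random intercept per marker.  With ``fixed_intercept=True`` an
    intercept column is prepended to every design; the identifiable
    alternative (``False``) lets the mixture means play the intercept
    role, since a fixed intercept and free random-intercept means are
    only jointly identified.
    """

    markers: list[MarkerSpec]
    fixed_effects: dict[str, list[str]] = field(default_factory=dict)
    K: int = 2
    random_effects: str = "intercept"
    fixed_intercept: bool = True

    def __post_init__(self):
        if self.random_effects != "intercept":
            raise ValidationError(
                "only the per-marker random-intercept structure is supported"
            )
        for m in self.markers:
            self.fixed_effects.setdefault(m.name, [])
            if not self.fixed_intercept and not self.fixed_effects[m.name]:
                raise ValidationError(
                    f"marker {m.name!r}: empty design (no intercept, no covariates)"
                )

    @property
    def q(self) -> int:
        return len(self.markers)

    def n_coefs(self, marker: str) -> int:
        return int(self.fixed_intercept) + len(self.fixed_effects[marker])

    def to_dict(self) -> dict:
        return {
            "markers": [{"name": m.name, "family": m.family} for m in self.markers],
            "fixed_effects": self.fixed_effects,
            "K": self.K,
            "random_effects": self.random_effects,
            "fixed_intercept": self.fixed_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            markers=[MarkerSpec(m["name"], m["family"]) for m in d["markers"]],
            fixed_effects={k: list(v) for k, v in d["fixed_effects"].items()},
            K=int(d.get("K", 2)),
            random_effects=d.get("random_effects", "intercept"),
            fixed_intercept=bool(d.get("fixed_intercept", True)),
        )


@dataclass
class Priors:
    """Weakly informative proper priors; all overridable."""

    alpha_var: float = 100.0  # alpha ~ N(0, alpha_var I)
    phi_shape: float = 0.01  # gaussian phi ~ InvGamma(shape, rate)
    phi_rate: float = 0.01
    dirichlet: float = 1.0  # w ~ Dirichlet(dirichlet * 1)
    mu_var: float = 100.0  # mu_k ~ N(0, mu_var I)
    wishart_df_add: float = 2.0  # D_k ~ InvWishart(q + df_add, scale * I)
    wishart_scale: float = 1.0


@dataclass
class GroupDraws:
    """Stacked posterior draws for one group (arrays indexed by draw m)."""

    alpha: dict[str, np.ndarray]  # marker -> (M, p_r)
    phi: dict[str, np.ndarray]  # marker -> (M,)
    weights: np.ndarray  # (M, K)
    means: np.ndarray  # (M, K, q)
    covs: np.ndarray  # (M, K, q, q)

    @property
    def M(self) -> int:
        return int(self.weights.shape[0])

    def get(self, m: int) -> GroupParams:
        return GroupParams(
            coefs={k: v[m] for k, v in self.alpha.items()},
            dispersions={k: float(v[m]) for k, v in self.phi.items()},
            mixture=MixtureParams(self.weights[m], self.means[m], self.covs[m]),
        )


@dataclass
class PosteriorDraws:
    """Joint MCMC sample of all groups' parameters plus diagnostics."""

    groups: list[GroupDraws]
    config: ModelConfig
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.groups[0].M

    @property
    def G(self) -> int:
        return len(self.groups)

    def get(self, m: int) -> list[GroupParams]:
        return [g.get(m) for g in self.groups]


# ---------------------------------------------------------------------------
# design matrices and observation likelihoods
# ---------------------------------------------------------------------------


def _covariate_column(history: HistorySlice, name: str) -> np.ndarray:
    if name == "time":
        return history.times
    if name not in history.patient.covariates:
        raise ValidationError(
            f"unknown covariate {name!r} for patient {history.patient.patient_id!r}"
        )
    return history.covariates(name)


def build_design(history: HistorySlice, config: ModelConfig, group: int = 0):
    """Per-marker response vectors and design matrices for one history.

    Returns ``{marker: (y, X, re_index)}`` using only visits where the
    marker was observed.  ``re_index`` is the position of the marker's
    random intercept within the random-effect vector (the z-vector is
    the corresponding unit basis vector).  The design structure is
    shared across groups; ``group`` selects nothing today but keeps the
    per-group hook in the signature.
    """
    out = {}
    for r, m in enumerate(config.markers):
        y = history.observations(m.name)
        keep = ~np.isnan(y)
        cols = [np.ones(history.n_visits)] if config.fixed_intercept else []
        for name in config.fixed_effects[m.name]:
            cols.append(_covariate_column(history, name))
        X = np.column_stack(cols)[keep]
        out[m.name] = (y[keep], X, r)
    return out


def obs_loglik(y, eta, family: str | MarkerSpec, phi: float = 1.0):
    """Exponential-family log-density at ``y`` with linear predictor ``eta``.

    gaussian: N(eta, phi); bernoulli: p = logistic(eta); poisson:
    lambda = exp(eta).  Broadcasts over arrays.
    """
    if isinstance(family, MarkerSpec):
        family = family.family
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if family == "gaussian":
        phi = np.asarray(phi, dtype=float)
        if np.any(phi <= 0):
            raise ValidationError("gaussian dispersion must be > 0")
        return -0.5 * (np.log(2 * np.pi * phi) + (y - eta) ** 2 / phi)
    if family == "bernoulli":
        # y*eta - log(1 + e^eta), stable for large |eta|
        return y * eta - np.logaddexp(0.0, eta)
    if family == "poisson":
        return y * eta - np.exp(eta) - gammaln(y + 1.0)
    raise ValidationError(f"unknown family {family!r}")


def _mvn_logpdf(b: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """N(mean, cov) log-density for rows of ``b`` (shape (..., q))."""
    b = np.atleast_2d(b)
    q = b.shape[-1]
    L = np.linalg.cholesky(cov)
    diff = b - mean
    u = np.linalg.solve(L, diff.T)
    maha = np.sum(u * u, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (q * np.log(2 * np.pi) + logdet + maha)


def mixture_logpdf(b: np.ndarray, mix: MixtureParams) -> np.ndarray:
    """log sum_k w_k N(b; mu_k, D_k), via log-sum-exp; vectorised over rows."""
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if b.shape[-1] != mix.dim:
        raise ValidationError(
            f"random-effect dimension {b.shape[-1]} != mixture dimension {mix.dim}"
        )
    parts = []
    for k in range(mix.K):
        try:
            parts.append(np.log(mix.weights[k]) + _mvn_logpdf(b, mix.means[k], mix.covs[k]))
        except np.linalg.LinAlgError as e:
            raise ValidationError(f"singular mixture covariance (component {k})") from e
    out = logsumexp(np.stack(parts, axis=0), axis=0)
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class _FlatGroup:
    """Flattened observations of all patients in one training group."""

    def __init__(self, patients, config: ModelConfig):
        self.n = len(patients)
        self.config = config
        self.y: dict[str, np.ndarray] = {}
        self.X: dict[str, np.ndarray] = {}
        self.pat: dict[str, np.ndarray] = {}
        for m in config.markers:
            ys, Xs, idx = [], [], []
            for i, p in enumerate(patients):
                h = HistorySlice(p, p.times[-1])
                y, X, _ = build_design(h, config)[m.name]
                ys.append(y)
                Xs.append(X)
                idx.append(np.full(y.size, i))
            self.y[m.name] = np.concatenate(ys)
            self.X[m.name] = np.vstack(Xs)
            self.pat[m.name] = np.concatenate(idx).astype(np.intp)


def _init_coefs(flat: _FlatGroup, config: ModelConfig):
    """Fixed-effects-only GLM fits for starting values (statsmodels)."""
    import statsmodels.api as sm

    fams = {
        "gaussian": sm.families.Gaussian(),
        "bernoulli": sm.families.Binomial(),
        "poisson": sm.families.Poisson(),
    }
    alpha, phi = {}, {}
    for m in config.markers:
        y, X = flat.y[m.name], flat.X[m.name]
        try:
            with np.errstate(all="ignore"):
                fit = sm.GLM(y, X, family=fams[m.family]).fit(maxiter=50)
                a = np.asarray(fit.params, dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError
            a = np.clip(a, -10.0, 10.0)
        except Exception:
            a = np.zeros(X.shape[1])
        alpha[m.name] = a
        if m.family == "gaussian":
            resid = y - X @ a
            phi[m.name] = float(max(np.var(resid), 1e-2))
        else:
            phi[m.name] = 1.0
    return alpha, phi


def _patient_loglik(flat: _FlatGroup, config: ModelConfig, alpha, phi, b) -> np.ndarray:
    """Observation log-likelihood summed per patient, given random effects."""
    total = np.zeros(flat.n)
    for r, m in enumerate(config.markers):
        eta = flat.X[m.name] @ alpha[m.name] + b[flat.pat[m.name], r]
        ll = obs_loglik(flat.y[m.name], eta, m.family, phi[m.name])
        total += np.bincount(flat.pat[m.name], weights=ll, minlength=flat.n)
    return total


def _marker_loglik(flat: _FlatGroup, m: MarkerSpec, r: int, a, phi, b) -> float:
    eta = flat.X[m.name] @ a + b[flat.pat[m.name], r]
    return float(np.sum(obs_loglik(flat.y[m.name], eta, m.family, phi)))


def _component_logliks(b, weights, means, covs):
    """(n, K) matrix of log w_k + log N(b_i; mu_k, D_k)."""
    K = weights.size
    cols = [
        np.log(weights[k]) + _mvn_logpdf(b, means[k], covs[k]) for k in range(K)
    ]
    return np.stack(cols, axis=1)


def _sample_group(flat: _FlatGroup, config: ModelConfig, priors: Priors,
                  n_iter: int, n_burn: int, thin: int, rng: np.random.Generator):
    q, K = config.q, config.K
    n = flat.n

    alpha, phi = _init_coefs(flat, config)
    b = np.zeros((n, q))
    weights = np.full(K, 1.0 / K)
    means = 0.1 * rng.standard_normal((K, q))
    covs = np.tile(np.eye(q), (K, 1, 1))
    s = rng.integers(0, K, size=n)

    lp0 = _patient_loglik(flat, config, alpha, phi, b)
    if not np.all(np.isfinite(lp0)):
        raise ValidationError("non-finite log-posterior at initialisation")

    # adaptive RW-MH state
    log_step_b = np.full(n, np.log(0.5))
    ng_markers = [(r, m) for r, m in enumerate(config.markers) if m.family != "gaussian"]
    log_step_a = {m.name: np.log(0.1) for _, m in ng_markers}
    prop_chol = {}
    for _, m in ng_markers:
        X = flat.X[m.name]
        info = X.T @ X + 1e-6 * np.eye(X.shape[1])
        prop_chol[m.name] = np.linalg.cholesky(np.linalg.inv(info))

    M = (n_iter - n_burn) // thin
    draws = GroupDraws(
        alpha={m.name: np.empty((M, alpha[m.name].size)) for m in config.markers},
        phi={m.name: np.empty(M) for m in config.markers},
        weights=np.empty((M, K)),
        means=np.empty((M, K, q)),
        covs=np.empty((M, K, q, q)),
    )
    acc_b_post, acc_a_post = [], {m.name: [] for _, m in ng_markers}

    patient_ll = _patient_loglik(flat, config, alpha, phi, b)
    df0 = q + priors.wishart_df_add
    S0 = priors.wishart_scale * np.eye(q)

    kept = 0
    for it in range(n_iter):
        gamma = min(0.1, 10.0 / (it + 10))  # Robbins-Monro adaptation rate

        # -- component allocations --------------------------------------
        logp = _component_logliks(b, weights, means, covs)
        g = logp + rng.gumbel(size=logp.shape)
        s = np.argmax(g, axis=1)

        # -- mixture weights ---------------------------------------------
        counts = np.bincount(s, minlength=K).astype(float)
        weights = rng.dirichlet(priors.dirichlet + counts)

        # -- mixture means and covariances -------------------------------
        for k in range(K):
            members = b[s == k]
            nk = members.shape[0]
            Dinv = np.linalg.inv(covs[k])
            V = np.linalg.inv(nk * Dinv + np.eye(q) / priors.mu_var)
            mean_k = V @ Dinv @ members.sum(axis=0) if nk else np.zeros(q)
            means[k] = rng.multivariate_normal(mean_k, V)
            dev = members - means[k]
            scatter = dev.T @ dev if nk else np.zeros((q, q))
            covs[k] = invwishart.rvs(df=df0 + nk, scale=S0 + scatter, random_state=rng)
            covs[k] = np.atleast_2d(covs[k])

        # -- random effects (per-patient adaptive RW-MH) ------------------
        prior_ll = _component_logliks(b, weights, means, covs)[np.arange(n), s]
        prop = b + np.exp(log_step_b)[:, None] * rng.standard_normal((n, q))
        prop_patient_ll = _patient_loglik(flat, config, alpha, phi, prop)
        prop_prior_ll = _component_logliks(prop, weights, means, covs)[np.arange(n), s]
        with np.errstate(invalid="ignore"):
            log_acc = (prop_patient_ll + prop_prior_ll) - (patient_ll + prior_ll)
        acc_prob = np.exp(np.minimum(0.0, np.nan_to_num(log_acc, nan=-np.inf)))
        accept = rng.random(n) < acc_prob
        b[accept] = prop[accept]
        patient_ll[accept] = prop_patient_ll[accept]
        if it < n_burn:
            log_step_b += gamma * (acc_prob - 0.30)
        else:
            acc_b_post.append(acc_prob.mean())

        # -- regression coefficients and dispersions ----------------------
        for r, m in enumerate(config.markers):
            y, X, pat = flat.y[m.name], flat.X[m.name], flat.pat[m.name]
            if m.family == "gaussian":
                u = y - b[pat, r]
                prec = X.T @ X / phi[m.name] + np.eye(X.shape[1]) / priors.alpha_var
                V = np.linalg.inv(prec)
                mean_a = V @ (X.T @ u) / phi[m.name]
                alpha[m.name] = rng.multivariate_normal(mean_a, V)
                resid = u - X @ alpha[m.name]
                shape = priors.phi_shape + 0.5 * y.size
                rate = priors.phi_rate + 0.5 * float(resid @ resid)
                phi[m.name] = float(rate / rng.gamma(shape))
            else:
                a = alpha[m.name]
                step = np.exp(log_step_a[m.name])
                prop_a = a + step * (prop_chol[m.name] @ rng.standard_normal(a.size))
                cur = _marker_loglik(flat, m, r, a, 1.0, b)
                new = _marker_loglik(flat, m, r, prop_a, 1.0, b)
                cur += -0.5 * float(a @ a) / priors.alpha_var
                new += -0.5 * float(prop_a @ prop_a) / priors.alpha_var
                ap = float(np.exp(min(0.0, new - cur))) if np.isfinite(new) else 0.0
                if rng.random() < ap:
                    alpha[m.name] = prop_a
                if it < n_burn:
                    log_step_a[m.name] += gamma * (ap - 0.30)
                else:
                    acc_a_post[m.name].append(ap)
        if any(m.family == "gaussian" for m in config.markers):
            # gaussian alpha changed -> refresh cached per-patient loglik
            patient_ll = _patient_loglik(flat, config, alpha, phi, b)

        # -- store ---------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            for m in config.markers:
                draws.alpha[m.name][kept] = alpha[m.name]
                draws.phi[m.name][kept] = phi[m.name]
            draws.weights[kept] = weights
            draws.means[kept] = means
            draws.covs[kept] = covs
            kept += 1

    diag = {"accept_b": float(np.mean(acc_b_post)) if acc_b_post else float("nan")}
    for name, lst in acc_a_post.items():
        diag[f"accept_alpha_{name}"] = float(np.mean(lst)) if lst else float("nan")
    return draws, diag


def fit_mglmm(train: Dataset, config: ModelConfig, n_iter: int = 2000,
              n_burn: int | None = None, thin: int = 1, seed: int = 0,
              priors: Priors | None = None) -> PosteriorDraws:
    """Fit the group-specific MGLMMs by MCMC; groups fitted independently.

    Returns ``(n_iter - n_burn) // thin`` joint draws per group.
    ``n_burn`` defaults to ``n_iter // 2``.
    """
    priors = priors or Priors()
    if n_burn is None:
        n_burn = n_iter // 2
    group_draws, diagnostics = [], {}
    for g in range(train.n_groups):
        patients = [p for p in train.patients if p.true_group == g]
        if not patients:
            raise ValidationError(f"no training patients in group {g}")
        unlabelled = [p.patient_id for p in train.patients if p.true_group is None]
        if unlabelled:
            raise ValidationError(f"unlabelled training patients: {unlabelled[:3]}")
        flat = _FlatGroup(patients, config)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(g,)))
        draws, diag = _sample_group(flat, config, priors, n_iter, n_burn, thin, rng)
        group_draws.append(draws)
        diagnostics[f"group{g}"] = diag
    return PosteriorDraws(groups=group_draws, config=config, seed=seed,
                          diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# serialisation (single npz archive + embedded JSON metadata)
# ---------------------------------------------------------------------------


def save_draws(draws: PosteriorDraws, path) -> None:
    arrays = {}
    for g, gd in enumerate(draws.groups):
        for name, arr in gd.alpha.items():
            arrays[f"g{g}_alpha_{name}"] = arr
        for name, arr in gd.phi.items():
            arrays[f"g{g}_phi_{name}"] = arr
        arrays[f"g{g}_weights"] = gd.weights
        arrays[f"g{g}_means"] = gd.means
        arrays[f"g{g}_covs"] = gd.covs
    meta = {
        "config": draws.config.to_dict(),
        "seed": draws.seed,
        "diagnostics": draws.diagnostics,
        "G": draws.G,
    }
    arrays["metadata"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_draws(path) -> PosteriorDraws:
    with np.load(path) as z:
        meta = json.loads(bytes(z["metadata"]).decode())
        config = ModelConfig.from_dict(meta["config"])
        groups = []
        for g in range(meta["G"]):
            groups.append(
                GroupDraws(
                    alpha={m.name: z[f"g{g}_alpha_{m.name}"] for m in config.markers},
                    phi={m.name: z[f"g{g}_phi_{m.name}"] for m in config.markers},
                    weights=z[f"g{g}_weights"],
                    means=z[f"g{g}_means"],
                    covs=z[f"g{g}_covs"],
                )
            )
    return PosteriorDraws(groups=groups, config=config, seed=meta["seed"],
                          diagnostics=meta["diagnostics"])
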