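"""Synthetic-data generator mirroring the MGLMM's generative assumptions.

Each simulated patient receives a prognostic group from the prevalence
vector, a random-effect vector from that group's normal mixture, an
irregular visit schedule inside the horizon, and per-visit marker
observations drawn from the configured exponential families with mean
``h_r(x' alpha + b_r)``.  The default configuration emulates the
structure of an epilepsy prognosis study: two groups at 90/10
prevalence and three markers — a binary seizure indicator (logit), a
log-transformed seizure count (gaussian) and an adverse-event count
(Poisson log) — with correlated random intercepts from a two-component
mixture per group.  Ground-truth parameters and random effects are
returned alongside the data for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_data import Dataset, MarkerSpec, PatientRecord, ValidationError
from .mglmm import GroupParams, MixtureParams, ModelConfig

__all__ = [
    "VisitModel",
    "SimConfig",
    "simulate_dataset",
    "default_sanad_like_config",
    "write_truth",
]


@dataclass
class VisitModel:
    """Irregular schedules: visit count uniform on {n_min..n_max}, gaps
    exponential with the given mean, truncated at the horizon."""

    n_min: int = 3
    n_max: int = 12
    gap_mean: float | None = None  # default horizon / 8


@dataclass
class SimConfig:
    """Full generative specification; the ground truth of a simulation."""

    n_patients: int
    prevalences: np.ndarray
    markers: list[MarkerSpec]
    group_params: list[GroupParams]
    fixed_effects: dict[str, list[str]]
    horizon: float = 5.0
    visit_model: VisitModel = field(default_factory=VisitModel)
    #: covariate name -> ("normal", mean, sd) or ("bernoulli", p); baseline
    covariate_sim: dict[str, tuple] = field(default_factory=dict)
    #: when False the mixture means act as intercepts (identifiable form)
    fixed_intercept: bool = False
    seed: int = 0

    def __post_init__(self):
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        if not np.isclose(self.prevalences.sum(), 1.0) or np.any(self.prevalences < 0):
            raise ValidationError("prevalences must form a simplex")
        if len(self.group_params) != self.prevalences.size:
            raise ValidationError("one GroupParams per group required")
        q = len(self.markers)
        for g, gp in enumerate(self.group_params):
            if gp.mixture.dim != q:
                raise ValidationError(f"group {g}: mixture dim != number of markers")

    def model_config(self, K: int | None = None) -> ModelConfig:
        """The fitting configuration matching this generative truth."""
        return ModelConfig(
            markers=list(self.markers),
            fixed_effects={k: list(v) for k, v in self.fixed_effects.items()},
            K=K if K is not None else self.group_params[0].mixture.K,
            fixed_intercept=self.fixed_intercept,
        )


def _draw_mixture(mix: MixtureParams, rng: np.random.Generator) -> np.ndarray:
    k = rng.choice(mix.K, p=mix.weights)
    L = np.linalg.cholesky(mix.covs[k])
    return mix.means[k] + L @ rng.standard_normal(mix.dim)


def _draw_times(vm: VisitModel, horizon: float, rng: np.random.Generator) -> np.ndarray:
    n = int(rng.integers(vm.n_min, vm.n_max + 1))
    gap_mean = vm.gap_mean if vm.gap_mean is not None else horizon / 8.0
    times = np.cumsum(rng.exponential(gap_mean, size=n))
    times = times[times < horizon]
    if times.size == 0:
        times = np.array([rng.uniform(0.05, 0.5) * horizon])
    return times


def _draw_marker(family: str, eta: np.ndarray, phi: float,
                 rng: np.random.Generator) -> np.ndarray:
    if family == "gaussian":
        return eta + np.sqrt(phi) * rng.standard_normal(eta.shape)
    if family == "bernoulli":
        return rng.binomial(1, expit(eta)).astype(float)
    if family == "poisson":
        return rng.poisson(np.exp(np.clip(eta, None, 30.0))).astype(float)
    raise ValidationError(f"unknown family {family!r}")


def simulate_dataset(config: SimConfig) -> tuple[Dataset, dict]:
    """Generate a dataset plus a ground-truth record.

    The truth record holds each patient's group and random-effect
    vector; the true parameters live in ``config.group_params``.
    """
    patients = []
    truth_groups: dict[str, int] = {}
    truth_b: dict[str, list] = {}
    for i in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        g = int(rng.choice(config.prevalences.size, p=config.prevalences))
        gp = config.group_params[g]
        b = _draw_mixture(gp.mixture, rng)
        times = _draw_times(config.visit_model, config.horizon, rng)
        covariates = {}
        for name, spec in config.covariate_sim.items():
            kind = spec[0]
            if kind == "normal":
                v = rng.normal(spec[1], spec[2])
            elif kind == "bernoulli":
                v = float(rng.binomial(1, spec[1]))
            else:
                raise ValidationError(f"unknown covariate generator {kind!r}")
            covariates[name] = np.full(times.size, v)
        observations = {}
        for r, m in enumerate(config.markers):
            cols = [np.ones(times.size)] if config.fixed_intercept else []
            for name in config.fixed_effects.get(m.name, []):
                cols.append(times if name == "time" else covariates[name])
            X = np.column_stack(cols)
            eta = X @ gp.coefs[m.name] + b[r]
            observations[m.name] = _draw_marker(m.family, eta,
                                                gp.dispersions[m.name], rng)
        pid = f"P{i:04d}"
        patients.append(
            PatientRecord(
                patient_id=pid, times=times, observations=observations,
                covariates=covariates, true_group=g, horizon=config.horizon,
            )
        )
        truth_groups[pid] = g
        truth_b[pid] = [float(x) for x in b]
    dataset = Dataset(
        patients=patients, markers=list(config.markers),
        n_groups=config.prevalences.size, prevalences=config.prevalences.copy(),
    )
    truth = {"group": truth_groups, "random_effects": truth_b, "seed": config.seed}
    return dataset, truth


def default_sanad_like_config(n_patients: int, seed: int = 0) -> SimConfig:
    """Two-group, three-marker template at 90/10 prevalence.

    The disease-free group's seizure odds and counts decline over
    follow-up while the disease group's stay high, so late histories
    separate the groups sharply; the random-intercept mixtures add
    realistic between-patient heterogeneity within each group.  The
    identifiable parameterisation is used: regression coefficients hold
    the time slopes, the mixture means carry the marker intercepts.
    """
    if n_patients < 2:
        raise ValidationError("need at least 2 patients")
    markers = [
        MarkerSpec("seizure", "bernoulli"),
        MarkerSpec("log_seizures", "gaussian"),
        MarkerSpec("adverse_events", "poisson"),
    ]
    D_base = np.array(
        [[0.35, 0.10, 0.05],
         [0.10, 0.30, 0.05],
         [0.05, 0.05, 0.30]]
    )
    remission = GroupParams(
        coefs={
            "seizure": np.array([-0.8]),
            "log_seizures": np.array([-0.15]),
            "adverse_events": np.array([-0.25]),
        },
        dispersions={"seizure": 1.0, "log_seizures": 0.4, "adverse_events": 1.0},
        mixture=MixtureParams(
            weights=np.array([0.6, 0.4]),
            means=np.array([[-0.9, 0.4, 0.0], [0.1, 1.15, 0.5]]),
            covs=np.stack([D_base, 0.8 * D_base]),
        ),
    )
    refractory = GroupParams(
        coefs={
            "seizure": np.array([0.05]),
            "log_seizures": np.array([0.05]),
            "adverse_events": np.array([0.05]),
        },
        dispersions={"seizure": 1.0, "log_seizures": 0.5, "adverse_events": 1.0},
        mixture=MixtureParams(
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.8, 1.45, 0.55], [1.8, 2.15, 1.05]]),
            covs=np.stack([D_base, D_base]),
        ),
    )
    return SimConfig(
        n_patients=n_patients,
        prevalences=np.array([0.9, 0.1]),
        markers=markers,
        group_params=[remission, refractory],
        fixed_effects={m.name: ["time"] for m in markers},
        horizon=5.0,
        seed=seed,
    )


def write_truth(truth: dict, config: SimConfig, path) -> None:
    """JSON sidecar: per-patient truth plus the true parameter values."""
    payload = dict(truth)
    payload["group_params"] = [
        {
            "coefs": {k: list(map(float, v)) for k, v in gp.coefs.items()},
            "dispersions": {k: float(v) for k, v in gp.dispersions.items()},
            "mixture": {
                "weights": gp.mixture.weights.tolist(),
                "means": gp.mixture.means.tolist(),
                "covs": gp.mixture.covs.tolist(),
            },
        }
        for gp in config.group_params
    ]
    payload["prevalences"] = config.prevalences.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
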