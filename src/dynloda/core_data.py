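"""Domain types and long-format file IO.

A dataset is a collection of patients, each observed at irregular visit
times before a fixed horizon ``T`` at which the true prognostic group
becomes observable.  At every visit one or more longitudinal markers of
mixed type (continuous, binary, count) are recorded together with
time-varying or baseline covariates.  Classification of a new patient at
time ``t`` may use only the history gathered by ``t``, which is what
:class:`HistorySlice` exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSpec",
    "PatientRecord",
    "Dataset",
    "HistorySlice",
    "SchemaError",
    "ValidationError",
    "slice_history",
    "read_dataset",
    "write_dataset",
]

#: marker family -> canonical link
CANONICAL_LINKS = {"gaussian": "identity", "bernoulli": "logit", "poisson": "log"}


class SchemaError(ValueError):
    """A column mapping does not match the file being read."""


class ValidationError(ValueError):
    """Data violate a domain invariant (ordering, family domain, ...)."""


@dataclass(frozen=True)
class MarkerSpec:
    """One longitudinal marker: its name, response family and link.

    Only canonical links are supported: gaussian/identity,
    bernoulli/logit, poisson/log.
    """

    name: str
    family: str
    link: str = ""

    def __post_init__(self):
        if self.family not in CANONICAL_LINKS:
            raise ValidationError(
                f"unknown family {self.family!r} for marker {self.name!r}"
            )
        canonical = CANONICAL_LINKS[self.family]
        link = self.link or canonical
        if link != canonical:
            raise ValidationError(
                f"marker {self.name!r}: family {self.family!r} requires the "
                f"{canonical!r} link, got {link!r}"
            )
        object.__setattr__(self, "link", link)

    def validate_values(self, y: np.ndarray) -> None:
        """Check observed (non-missing) values against the family domain."""
        y = np.asarray(y, dtype=float)
        obs = y[~np.isnan(y)]
        if self.family == "bernoulli" and not np.all(np.isin(obs, (0.0, 1.0))):
            raise ValidationError(f"marker {self.name!r}: bernoulli values must be 0/1")
        if self.family == "poisson":
            if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
                raise ValidationError(
                    f"marker {self.name!r}: poisson values must be non-negative integers"
                )


@dataclass
class PatientRecord:
    """One subject's visit history.

    Parameters
    ----------
    patient_id
        Unique identifier.
    times
        Strictly increasing visit times, all below ``horizon``.
    observations
        Marker name -> per-visit values; ``nan`` marks a marker not
        observed at that visit.
    covariates
        Covariate name -> per-visit values (baseline covariates are
        simply constant across visits).
    true_group
        Known prognostic group (training data) or ``None``.
    horizon
        Time ``T`` at which the true group becomes observable.
    """

    patient_id: str
    times: np.ndarray
    observations: dict[str, np.ndarray]
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    true_group: int | None = None
    horizon: float = 5.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 1:
            raise ValidationError(f"patient {self.patient_id!r}: needs at least one visit")
        if not np.all(np.isfinite(self.times)):
            raise ValidationError(f"patient {self.patient_id!r}: non-finite visit time")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"patient {self.patient_id!r}: visit times must be strictly increasing"
            )
        if not self.horizon > 0:
            raise ValidationError(f"patient {self.patient_id!r}: horizon must be > 0")
        if self.times[-1] >= self.horizon:
            raise ValidationError(
                f"patient {self.patient_id!r}: visit at {self.times[-1]} is not "
                f"before the horizon {self.horizon}"
            )
        n = self.times.size
        self.observations = {
            k: np.asarray(v, dtype=float) for k, v in self.observations.items()
        }
        self.covariates = {
            k: np.asarray(v, dtype=float) for k, v in self.covariates.items()
        }
        for k, v in {**self.observations, **self.covariates}.items():
            if v.shape != (n,):
                raise ValidationError(
                    f"patient {self.patient_id!r}: column {k!r} has length "
                    f"{v.size}, expected {n}"
                )

    @property
    def n_visits(self) -> int:
        return int(self.times.size)


@dataclass
class Dataset:
    """Patients plus marker specifications and group structure."""

    patients: list[PatientRecord]
    markers: list[MarkerSpec]
    n_groups: int = 2
    #: simplex of length ``n_groups``, or ``None`` = estimate from data
    prevalences: np.ndarray | None = None

    def __post_init__(self):
        if self.prevalences is not None:
            self.prevalences = np.asarray(self.prevalences, dtype=float)
            if self.prevalences.shape != (self.n_groups,) or not np.isclose(
                self.prevalences.sum(), 1.0
            ):
                raise ValidationError("prevalences must be a simplex of length n_groups")
        names = {m.name for m in self.markers}
        for p in self.patients:
            missing = names - set(p.observations)
            if missing:
                raise ValidationError(
                    f"patient {p.patient_id!r}: missing markers {sorted(missing)}"
                )
            for m in self.markers:
                m.validate_values(p.observations[m.name])
            if p.true_group is not None and not 0 <= p.true_group < self.n_groups:
                raise ValidationError(
                    f"patient {p.patient_id!r}: group {p.true_group} outside "
                    f"0..{self.n_groups - 1}"
                )

    def estimated_prevalences(self) -> np.ndarray:
        """Known prevalences, or training-set group proportions."""
        if self.prevalences is not None:
            return self.prevalences
        labels = [p.true_group for p in self.patients if p.true_group is not None]
        if not labels:
            raise ValidationError("no labelled patients to estimate prevalences from")
        counts = np.bincount(labels, minlength=self.n_groups).astype(float)
        return counts / counts.sum()

    def subset(self, ids: Sequence[str]) -> "Dataset":
        keep = set(ids)
        return Dataset(
            patients=[p for p in self.patients if p.patient_id in keep],
            markers=self.markers,
            n_groups=self.n_groups,
            prevalences=self.prevalences,
        )


@dataclass
class HistorySlice:
    """The part of a patient's record gathered by time ``t`` (closed at t)."""

    patient: PatientRecord
    t: float

    def __post_init__(self):
        if self.t < self.patient.times[0]:
            raise ValidationError(
                f"patient {self.patient.patient_id!r}: cutoff {self.t} precedes "
                f"the first visit at {self.patient.times[0]} (empty history)"
            )
        self._mask = self.patient.times <= self.t

    @property
    def times(self) -> np.ndarray:
        return self.patient.times[self._mask]

    @property
    def n_visits(self) -> int:
        return int(self._mask.sum())

    def observations(self, marker: str) -> np.ndarray:
        return self.patient.observations[marker][self._mask]

    def covariates(self, name: str) -> np.ndarray:
        return self.patient.covariates[name][self._mask]


def slice_history(patient: PatientRecord, t: float) -> HistorySlice:
    """Restrict ``patient`` to visits with time <= ``t``."""
    return HistorySlice(patient, float(t))


# ---------------------------------------------------------------------------
# long-format CSV IO
# ---------------------------------------------------------------------------


def _marker_specs_from_schema(schema: Mapping) -> list[MarkerSpec]:
    specs = []
    for name, info in schema["markers"].items():
        if isinstance(info, str):
            info = {"family": info}
        specs.append(MarkerSpec(name=name, family=info["family"]))
    return specs


def read_dataset(path, schema: Mapping) -> Dataset:
    """Read a long-format CSV (one row per patient visit) into a :class:`Dataset`.

    ``schema`` maps roles to column names::

        id: patient_id          # mandatory
        time: visit_time        # mandatory
        markers:                # mandatory; marker name -> family (or
          seizure: bernoulli    #   {family: ..., column: ...})
        covariates: [age]       # optional
        label: group            # optional (training label)
        horizon: 5.0            # scalar, or a column name
        n_groups: 2
        prevalences: [0.9, 0.1] # optional; omit to estimate from data
        standardize: [age]      # optional per-covariate centering/scaling
    """
    df = pd.read_csv(path, float_precision="round_trip")
    id_col, time_col = schema["id"], schema["time"]
    covs = list(schema.get("covariates", []))
    label_col = schema.get("label")
    marker_cols = {
        name: (info.get("column", name) if isinstance(info, Mapping) else name)
        for name, info in schema["markers"].items()
    }
    needed = [id_col, time_col, *marker_cols.values(), *covs]
    if label_col:
        needed.append(label_col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns {missing} in {path}")

    if not np.all(np.isfinite(df[time_col].to_numpy(dtype=float))):
        raise ValidationError("non-finite visit times present")
    dup = df.duplicated(subset=[id_col, time_col])
    if dup.any():
        who = df.loc[dup, id_col].iloc[0]
        raise ValidationError(f"duplicate (id, time) rows for patient {who!r}")

    for name in schema.get("standardize", []):
        x = df[name].to_numpy(dtype=float)
        sd = x.std()
        df[name] = (x - x.mean()) / (sd if sd > 0 else 1.0)

    horizon = schema.get("horizon", 5.0)
    horizon_col = horizon if isinstance(horizon, str) else None

    patients = []
    for pid, grp in df.groupby(id_col, sort=True):
        grp = grp.sort_values(time_col)
        label = None
        if label_col is not None and not grp[label_col].isna().all():
            label = int(grp[label_col].iloc[0])
        T = float(grp[horizon_col].iloc[0]) if horizon_col else float(horizon)
        patients.append(
            PatientRecord(
                patient_id=str(pid),
                times=grp[time_col].to_numpy(dtype=float),
                observations={
                    name: grp[col].to_numpy(dtype=float)
                    for name, col in marker_cols.items()
                },
                covariates={c: grp[c].to_numpy(dtype=float) for c in covs},
                true_group=label,
                horizon=T,
            )
        )
    return Dataset(
        patients=patients,
        markers=_marker_specs_from_schema(schema),
        n_groups=int(schema.get("n_groups", 2)),
        prevalences=schema.get("prevalences"),
    )


def write_dataset(dataset: Dataset, path, schema: Mapping | None = None) -> pd.DataFrame:
    """Write a dataset back to long-format CSV; returns the frame written."""
    schema = schema or {}
    id_col = schema.get("id", "patient_id")
    time_col = schema.get("time", "time")
    label_col = schema.get("label", "group")
    rows = []
    for p in dataset.patients:
        for j in range(p.n_visits):
            row = {id_col: p.patient_id, time_col: p.times[j]}
            for m in dataset.markers:
                row[m.name] = p.observations[m.name][j]
            for c, v in p.covariates.items():
                row[c] = v[j]
            row[label_col] = p.true_group if p.true_group is not None else np.nan
            row["horizon"] = p.horizon
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def default_schema(dataset: Dataset) -> dict:
    """Schema under which :func:`write_dataset` output round-trips."""
    return {
        "id": "patient_id",
        "time": "time",
        "markers": {m.name: m.family for m in dataset.markers},
        "covariates": sorted(
            dataset.patients[0].covariates.keys() if dataset.patients else []
        ),
        "label": "group",
        "horizon": "horizon",
        "n_groups": dataset.n_groups,
        "prevalences": None
        if dataset.prevalences is None
        else list(map(float, dataset.prevalences)),
    }
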