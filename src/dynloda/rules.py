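"""Allocation schemes mapping probability trajectories to group labels.

All schemes are dynamic: the patient is examined visit by visit and may
be classified into the disease group (1), the disease-free group (0) or
left unclassified (``None``).  Once a decisive label is issued the
classification is frozen — later visits never revise it.  The schemes:

``cutoff``
    classify at every visit by thresholding the point estimate.
``dynloda``
    disease whenever the point estimate exceeds the cutoff; disease-free
    only at the final visit.
``symmetric``
    three-zone rule around the cutoff (requires c > 0.5).
``two_consecutive``
    disease only after two consecutive exceedances.
``delta``
    disease when the probability jumps by more than ``k`` between visits.
``fixed_time``
    one prediction at a prespecified time.
``dynci``
    the credible-interval rule: disease only when the whole HPD interval
    sits above the cutoff, disease-free only when it sits below; in the
    ``disease_focus`` variant only the disease condition stops follow-up
    before the final visit.

Prediction time is the first visit with a decisive label (the horizon T
if there is none); lead time is the time remaining to the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import ValidationError
from .loda import ProbabilityTrajectory

__all__ = [
    "NA",
    "AllocationResult",
    "rule_cutoff",
    "rule_argmax",
    "rule_dynloda",
    "rule_symmetric",
    "rule_two_consecutive",
    "rule_delta",
    "rule_fixed_time",
    "rule_dynci",
    "prediction_and_lead_times",
    "apply_rule",
    "export_allocations",
]

#: the unclassified label
NA = None

DISEASE = 1  # index of the disease group in the two-group setting


@dataclass
class AllocationResult:
    """Per-visit labels, the frozen final label and timing of one patient."""

    patient_id: str
    times: np.ndarray
    labels: list  # int | None per visit
    final_label: object  # int | None
    t_pred: float
    t_lead: float
    rule: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t_lead < -1e-12:
            raise ValidationError("negative lead time")


def prediction_and_lead_times(labels, times, horizon: float):
    """First decisive visit time (or the horizon) and the remaining lead."""
    for lab, t in zip(labels, times):
        if lab is not NA:
            return float(t), float(horizon - t)
    return float(horizon), 0.0


def _freeze(labels):
    """Repeat the first decisive label over all later visits."""
    out, decided = [], NA
    for lab in labels:
        if decided is NA and lab is not NA:
            decided = lab
        out.append(lab if decided is NA else decided)
    return out


def _result(patient_id, times, labels, horizon, rule, params):
    labels = _freeze(labels)
    t_pred, t_lead = prediction_and_lead_times(labels, times, horizon)
    final = next((l for l in labels if l is not NA), NA)
    return AllocationResult(
        patient_id=patient_id,
        times=np.asarray(times, dtype=float),
        labels=labels,
        final_label=final,
        t_pred=t_pred,
        t_lead=t_lead,
        rule=rule,
        params=dict(params),
    )


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------


def rule_cutoff(p_d: float, c: float) -> int:
    """Threshold the disease probability; the boundary p = c maps to 0."""
    if not 0 < c < 1:
        raise ValidationError("cutoff must lie in (0, 1)")
    return 1 if p_d > c else 0


def rule_argmax(p: np.ndarray) -> int:
    """Classical most-probable-group assignment."""
    return int(np.argmax(p))


def rule_dynloda(times, p_d, c: float, horizon: float,
                 patient_id: str = "") -> AllocationResult:
    """Disease at any visit with p > c; disease-free only at the final visit."""
    times = np.asarray(times, dtype=float)
    p_d = np.asarray(p_d, dtype=float)
    n = times.size
    labels = []
    for j in range(n):
        if p_d[j] > c:
            labels.append(1)
        elif j == n - 1:
            labels.append(rule_cutoff(p_d[j], c))
        else:
            labels.append(NA)
    return _result(patient_id, times, labels, horizon, "dynloda", {"c": c})


def rule_symmetric(p_d: float, c: float):
    """Three-zone rule: 0 below 1-c, 1 above c, unclassified between."""
    if not c > 0.5:
        raise ValidationError("symmetric rule needs c > 0.5 (zones overlap otherwise)")
    if p_d < 1 - c:
        return 0
    if p_d > c:
        return 1
    return NA


def rule_two_consecutive(times, p_d, c: float, horizon: float,
                         patient_id: str = "") -> AllocationResult:
    """Disease after two consecutive exceedances; first visit always
    unclassified; an unresolved final visit becomes disease-free.

    A single-visit patient can never satisfy two consecutive
    exceedances, so the final-visit fallthrough assigns 0.
    """
    times = np.asarray(times, dtype=float)
    p_d = np.asarray(p_d, dtype=float)
    n = times.size
    labels = []
    for j in range(n):
        two = j >= 1 and p_d[j] > c and p_d[j - 1] > c
        if two:
            labels.append(1)
        elif j == n - 1:
            labels.append(0)
        else:
            labels.append(NA)
    return _result(patient_id, times, labels, horizon, "two_consecutive", {"c": c})


def rule_delta(times, p_d, k: float, horizon: float,
               patient_id: str = "") -> AllocationResult:
    """Disease at the first visit where p rises by strictly more than k."""
    if not k > 0:
        raise ValidationError("k must be > 0")
    times = np.asarray(times, dtype=float)
    p_d = np.asarray(p_d, dtype=float)
    n = times.size
    labels = []
    for j in range(n):
        jump = j >= 1 and (p_d[j] - p_d[j - 1]) > k
        if jump:
            labels.append(1)
        elif j == n - 1:
            labels.append(0)
        else:
            labels.append(NA)
    return _result(patient_id, times, labels, horizon, "delta", {"k": k})


def rule_fixed_time(times, p_d, t_pred: float, c: float, horizon: float,
                    patient_id: str = "") -> AllocationResult | None:
    """One prediction from the history gathered by ``t_pred``.

    Probabilities only change at visits, so the estimate at ``t_pred``
    is the one at the last visit at or before it.  Returns ``None``
    (skip flag) when the patient has no visit by ``t_pred``.
    """
    times = np.asarray(times, dtype=float)
    p_d = np.asarray(p_d, dtype=float)
    usable = np.nonzero(times <= t_pred)[0]
    if usable.size == 0:
        return None
    j = int(usable[-1])
    label = rule_cutoff(p_d[j], c)
    return AllocationResult(
        patient_id=patient_id,
        times=np.array([t_pred]),
        labels=[label],
        final_label=label,
        t_pred=float(t_pred),
        t_lead=float(horizon - t_pred),
        rule="fixed_time",
        params={"c": c, "t_pred": t_pred},
    )


def rule_dynci(times, low, upp, c: float, horizon: float,
               variant: str = "full", patient_id: str = "") -> AllocationResult:
    """Credible-interval rule: decisive only when the whole HPD interval
    clears the cutoff.

    ``full``: disease when low > c, disease-free when upp < c, else
    unclassified; follow-up stops at the first decisive visit.
    ``disease_focus``: only the disease condition stops follow-up early;
    at the final visit the label may be 1, 0 or remain unclassified.
    """
    if not 0 < c < 1:
        raise ValidationError("cutoff must lie in (0, 1)")
    if variant not in ("full", "disease_focus"):
        raise ValidationError(f"unknown dynci variant {variant!r}")
    times = np.asarray(times, dtype=float)
    low = np.asarray(low, dtype=float)
    upp = np.asarray(upp, dtype=float)
    n = times.size
    labels = []
    for j in range(n):
        final = j == n - 1
        if low[j] > c:
            labels.append(1)
        elif upp[j] < c and (variant == "full" or final):
            labels.append(0)
        else:
            labels.append(NA)
    return _result(patient_id, times, labels, horizon, "dynci",
                   {"c": c, "variant": variant})


# ---------------------------------------------------------------------------
# dispatch on trajectories
# ---------------------------------------------------------------------------


def apply_rule(traj: ProbabilityTrajectory, rule: str, *, c: float | None = None,
               k: float | None = None, t_pred: float | None = None,
               variant: str = "full", group: int = DISEASE):
    """Apply a named rule to a probability trajectory.

    ``dynci`` consumes the trajectory's HPD bounds (at the alpha the
    trajectory was built with); the point-estimate rules consume the
    posterior means.  Returns an :class:`AllocationResult`, or ``None``
    for a skipped fixed-time patient.
    """
    p, low, upp = traj.disease(group)
    common = dict(horizon=traj.horizon, patient_id=traj.patient_id)
    if rule == "argmax":
        labels = [rule_argmax(traj.means[j]) for j in range(traj.times.size)]
        return _result(traj.patient_id, traj.times, labels, traj.horizon,
                       "argmax", {})
    if rule == "cutoff":
        labels = [rule_cutoff(pj, c) for pj in p]
        return _result(traj.patient_id, traj.times, labels, traj.horizon,
                       "cutoff", {"c": c})
    if rule == "dynloda":
        return rule_dynloda(traj.times, p, c, **common)
    if rule == "symmetric":
        labels = [rule_symmetric(pj, c) for pj in p]
        return _result(traj.patient_id, traj.times, labels, traj.horizon,
                       "symmetric", {"c": c})
    if rule == "two_consecutive":
        return rule_two_consecutive(traj.times, p, c, **common)
    if rule == "delta":
        return rule_delta(traj.times, p, k, **common)
    if rule == "fixed_time":
        return rule_fixed_time(traj.times, p, t_pred, c, **common)
    if rule == "dynci":
        return rule_dynci(traj.times, low, upp, c, variant=variant, **common)
    raise ValidationError(f"unknown rule {rule!r}")


def export_allocations(results: list[AllocationResult], path) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "patient_id": r.patient_id,
                "rule": r.rule,
                "params": ";".join(f"{k}={v}" for k, v in r.params.items()),
                "labels": ";".join("NA" if l is NA else str(l) for l in r.labels),
                "final_label": "NA" if r.final_label is NA else int(r.final_label),
                "t_pred": r.t_pred,
                "t_lead": r.t_lead,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
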