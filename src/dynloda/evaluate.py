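"""Unclassified-aware accuracy evaluation and the cross-validation harness.

The confusion table has a third predicted column for unclassified
patients.  Accuracy metrics come in two modes: ``classified_only``
drops the unclassified column from every denominator (the accuracy of
the decisions actually made), while ``overall`` keeps unclassified
patients in the sensitivity/specificity/PCC denominators, treating an
abstention as a failure to detect for both groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_data import Dataset, ValidationError
from .loda import ProbabilityTrajectory, trajectory
from .mglmm import ModelConfig, fit_mglmm
from .rules import NA, AllocationResult, apply_rule

__all__ = [
    "ConfusionTable",
    "AccuracyReport",
    "RocPoint",
    "confusion",
    "metrics",
    "roc_over_cutoffs",
    "select_cutoff",
    "auc",
    "mean_times",
    "loo_cv",
    "CVResult",
    "DEFAULT_CUTOFF_GRID",
]

DEFAULT_CUTOFF_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class ConfusionTable:
    """G x (G+1) counts; rows = true group, last column = unclassified."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.counts.shape[0] + 1:
            raise ValidationError("confusion table must be G x (G+1)")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")

    @property
    def G(self) -> int:
        return int(self.counts.shape[0])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = [str(g) for g in range(self.G)] + ["unclassified"]
        return pd.DataFrame(self.counts, index=[str(g) for g in range(self.G)],
                            columns=cols)


def confusion(truth, predicted, n_groups: int = 2) -> ConfusionTable:
    """Count (true group, predicted label) pairs; ``None`` = unclassified."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValidationError("truth and prediction lengths differ")
    counts = np.zeros((n_groups, n_groups + 1), dtype=int)
    for t, p in zip(truth, predicted):
        if not (isinstance(t, (int, np.integer)) and 0 <= t < n_groups):
            raise ValidationError(f"true label {t!r} outside 0..{n_groups - 1}")
        if p is NA:
            counts[t, n_groups] += 1
        elif isinstance(p, (int, np.integer)) and 0 <= p < n_groups:
            counts[t, p] += 1
        else:
            raise ValidationError(f"predicted label {p!r} outside domain")
    return ConfusionTable(counts)


@dataclass
class AccuracyReport:
    """Accuracy metrics; a metric with zero denominator is NaN and its
    name is recorded in ``undefined`` rather than silently set to 0."""

    sensitivity: float
    specificity: float
    pcc: float
    ppv: float
    npv: float
    proportion_unclassified: float
    mode: str
    auc: float = math.nan
    mean_lead_time: float = math.nan
    mean_prediction_time: float = math.nan
    undefined: list = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> dict:
        """Metrics rounded half away from zero, the table convention."""
        out = {}
        for k, v in asdict(self).items():
            if isinstance(v, float) and not math.isnan(v):
                out[k] = math.copysign(
                    math.floor(abs(v) * 10**ndigits + 0.5) / 10**ndigits, v
                )
            else:
                out[k] = v
        return out


def _ratio(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def metrics(table: ConfusionTable, mode: str = "classified_only") -> AccuracyReport:
    """Two-group accuracy metrics from an unclassified-aware table.

    ``classified_only`` ignores the unclassified column entirely;
    ``overall`` adds the per-group unclassified counts to the
    sensitivity/specificity denominators and the grand total to PCC's.
    """
    if table.G != 2:
        raise ValidationError("metrics are defined for the two-group case")
    if mode not in ("classified_only", "overall"):
        raise ValidationError(f"unknown mode {mode!r}")
    tn, fp, u0 = table.counts[0]
    fn, tp, u1 = table.counts[1]
    und: list = []
    grand = table.total
    prop_na = _ratio(u0 + u1, grand, "proportion_unclassified", und)
    if mode == "classified_only":
        se = _ratio(tp, tp + fn, "sensitivity", und)
        sp = _ratio(tn, tn + fp, "specificity", und)
        pcc = _ratio(tp + tn, tp + tn + fp + fn, "pcc", und)
    else:
        se = _ratio(tp, tp + fn + u1, "sensitivity", und)
        sp = _ratio(tn, tn + fp + u0, "specificity", und)
        pcc = _ratio(tp + tn, grand, "pcc", und)
    ppv = _ratio(tp, tp + fp, "ppv", und)
    npv = _ratio(tn, tn + fn, "npv", und)
    return AccuracyReport(
        sensitivity=se, specificity=sp, pcc=pcc, ppv=ppv, npv=npv,
        proportion_unclassified=prop_na, mode=mode, undefined=und,
    )


# ---------------------------------------------------------------------------
# ROC, cutoff selection, AUC
# ---------------------------------------------------------------------------


@dataclass
class RocPoint:
    c: float
    sensitivity: float
    specificity: float
    pcc: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    proportion_unclassified: float = math.nan


def roc_over_cutoffs(trajs: list[ProbabilityTrajectory], rule: str,
                     grid=DEFAULT_CUTOFF_GRID, **rule_kwargs) -> list[RocPoint]:
    """Apply ``rule`` at every cutoff of ``grid`` to every trajectory.

    Metrics are computed in ``classified_only`` mode, which for rules
    without an unclassified zone coincides with the overall mode.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any((grid <= 0) | (grid >= 1)):
        raise ValidationError("cutoff grid must be non-empty and inside (0, 1)")
    labelled = [t for t in trajs if t.true_group is not None]
    points = []
    for c in grid:
        results = [apply_rule(t, rule, c=float(c), **rule_kwargs) for t in labelled]
        pairs = [(t.true_group, r.final_label)
                 for t, r in zip(labelled, results) if r is not None]
        tab = confusion([a for a, _ in pairs], [b for _, b in pairs])
        rep = metrics(tab, "classified_only")
        points.append(RocPoint(float(c), rep.sensitivity, rep.specificity,
                               rep.pcc, rep.ppv, rep.npv,
                               rep.proportion_unclassified))
    return points


def select_cutoff(roc: list[RocPoint], criterion: str = "d2") -> float:
    """Pick a cutoff from ROC points; ties go to the smallest cutoff.

    ``d2`` minimises (1-Se)^2 + (1-Sp)^2 (distance to the top-left
    corner); ``youden`` maximises Se + Sp - 1; ``max_pcc`` / ``max_ppv``
    / ``max_npv`` maximise the named metric.
    """
    if not roc:
        raise ValidationError("empty ROC")
    scores = {
        "d2": lambda p: -((1 - p.sensitivity) ** 2 + (1 - p.specificity) ** 2),
        "youden": lambda p: p.sensitivity + p.specificity - 1,
        "max_pcc": lambda p: p.pcc,
        "max_ppv": lambda p: p.ppv,
        "max_npv": lambda p: p.npv,
    }
    if criterion not in scores:
        raise ValidationError(f"unknown criterion {criterion!r}")
    best_c, best = None, -math.inf
    for p in sorted(roc, key=lambda p: p.c):
        s = scores[criterion](p)
        if not math.isnan(s) and s > best:
            best_c, best = p.c, s
    if best_c is None:
        raise ValidationError("all metrics undefined over the grid")
    return float(best_c)


def auc(roc: list[RocPoint]) -> float:
    """Trapezoidal area over (1-Sp, Se), endpoints (0,0)/(1,1) appended."""
    pts = [(1 - p.specificity, p.sensitivity) for p in roc
           if not (math.isnan(p.sensitivity) or math.isnan(p.specificity))]
    if len(pts) < 1:
        raise ValidationError("need at least one defined ROC point")
    pts = sorted(set(pts + [(0.0, 0.0), (1.0, 1.0)]))
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return float(np.trapezoid(y, x))


# ---------------------------------------------------------------------------
# timing summaries and cross-validation
# ---------------------------------------------------------------------------


def mean_times(results: list[AllocationResult], truth: dict[str, int] | None = None,
               which: str = "correct_disease_only") -> tuple[float, float]:
    """Mean (lead time, prediction time) over the filtered allocations.

    ``correct_disease_only`` keeps patients correctly identified as
    diseased (requires ``truth``); ``all`` keeps everyone.  Returns
    (nan, nan) when the filter leaves nothing.
    """
    if which == "correct_disease_only":
        if truth is None:
            raise ValidationError("truth labels needed for correct_disease_only")
        sel = [r for r in results
               if r.final_label == 1 and truth.get(r.patient_id) == 1]
    elif which == "all":
        sel = list(results)
    else:
        raise ValidationError(f"unknown filter {which!r}")
    if not sel:
        return math.nan, math.nan
    return (
        float(np.mean([r.t_lead for r in sel])),
        float(np.mean([r.t_pred for r in sel])),
    )


@dataclass
class CVResult:
    """Held-out trajectories, allocations and aggregate accuracy."""

    allocations: list[AllocationResult]
    trajectories: list[ProbabilityTrajectory]
    truth: dict[str, int]
    table: ConfusionTable
    classified_only: AccuracyReport
    overall: AccuracyReport
    n_fits: int
    excluded_single_visit: list[str] = field(default_factory=list)


def _make_folds(patients, k_fold, rng):
    """Stratified fold assignment (exact LOO when k_fold is None)."""
    if k_fold is None:
        return [[p.patient_id] for p in patients]
    by_group: dict[int, list[str]] = {}
    for p in patients:
        by_group.setdefault(p.true_group, []).append(p.patient_id)
    folds: list[list[str]] = [[] for _ in range(k_fold)]
    for ids in by_group.values():
        ids = list(ids)
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            folds[i % k_fold].append(pid)
    return [f for f in folds if f]


def loo_cv(dataset: Dataset, config: ModelConfig, rule: str, *,
           c: float | None = None, k: float | None = None,
           t_pred: float | None = None, variant: str = "full",
           alpha: float = 0.01, n_mc: int = 100, n_iter: int = 600,
           n_burn: int | None = None, thin: int = 1, seed: int = 0,
           k_fold: int | None = None) -> CVResult:
    """Leave-one-out (or k-fold approximate) cross-validated allocation.

    For each held-out patient the MGLMM is fitted on all other patients,
    the patient's probability trajectory is computed and ``rule`` is
    applied.  Patients with a single recorded visit are kept for fitting
    but excluded from prediction — a prediction history cannot be built
    for them.
    """
    labelled = [p for p in dataset.patients if p.true_group is not None]
    if len(labelled) != len(dataset.patients):
        raise ValidationError("cross-validation requires every patient labelled")
    predictable = [p for p in labelled if p.n_visits >= 2]
    excluded = [p.patient_id for p in labelled if p.n_visits < 2]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(987,)))
    folds = _make_folds(predictable, k_fold, rng)

    by_id = {p.patient_id: p for p in dataset.patients}
    allocations, trajs = [], []
    for f, fold_ids in enumerate(folds):
        hold = set(fold_ids)
        train = Dataset(
            patients=[p for p in dataset.patients if p.patient_id not in hold],
            markers=dataset.markers,
            n_groups=dataset.n_groups,
            prevalences=dataset.prevalences,
        )
        prev = train.estimated_prevalences()
        draws = fit_mglmm(train, config, n_iter=n_iter, n_burn=n_burn,
                          thin=thin, seed=seed + 10_000 + f)
        for pid in fold_ids:
            tr = trajectory(by_id[pid], draws, prev, alpha=alpha,
                            n_mc=n_mc, seed=seed)
            trajs.append(tr)
            res = apply_rule(tr, rule, c=c, k=k, t_pred=t_pred, variant=variant)
            if res is not None:
                allocations.append(res)

    truth = {p.patient_id: p.true_group for p in predictable}
    pairs = [(truth[r.patient_id], r.final_label) for r in allocations]
    tab = confusion([a for a, _ in pairs], [b for _, b in pairs],
                    n_groups=dataset.n_groups)
    rep_c = metrics(tab, "classified_only")
    rep_o = metrics(tab, "overall")
    lead, pred = mean_times(allocations, truth)
    for rep in (rep_c, rep_o):
        rep.mean_lead_time = lead
        rep.mean_prediction_time = pred
    return CVResult(
        allocations=allocations, trajectories=trajs, truth=truth, table=tab,
        classified_only=rep_c, overall=rep_o, n_fits=len(folds),
        excluded_single_visit=excluded,
    )
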