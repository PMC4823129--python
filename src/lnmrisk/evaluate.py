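"""Evaluation of a fitted risk model on a cohort.

Covers risk-group assignment, horizon-restricted confusion metrics
(sensitivity/specificity/PPV/NPV at a stated follow-up horizon, default
five years), ranking performance (AUC) of the continuous score,
Kaplan-Meier cumulative incidence of metastasis, the two-group log-rank
test, and the high- versus low-risk hazard ratio.

Censoring convention for the horizon metrics: a patient is a case if the
event occurred by the horizon, a control if followed event-free through
the horizon, and excluded from the denominator if censored event-free
before the horizon.  No inverse-probability-of-censoring weighting is
applied; reported metrics carry this convention explicitly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .model import RiskModel, total_scores, univariate_ph

logger = logging.getLogger(__name__)

LOW, HIGH = "low", "high"


def classify(patients: pd.DataFrame, model: RiskModel) -> pd.DataFrame:
    """Assign each patient a total score and a low/high risk group.

    Patients scoring exactly at the cutoff are low-risk: the group is high
    iff total_score > cutoff.
    """
    if model.cutoff is None:
        raise ValidationError("model has no cutoff; cannot classify")
    scores = total_scores(patients, model.score_table)
    if not (0 <= model.cutoff <= model.score_table.max_score):
        raise ValidationError(
            f"cutoff {model.cutoff} outside attainable score range [0, {model.score_table.max_score}]"
        )
    groups = np.where(scores.to_numpy() > model.cutoff, HIGH, LOW)
    out = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "total_score": scores.to_numpy(),
            "group": groups,
        }
    )
    logger.info(
        "classified %d patients: %d low-risk, %d high-risk",
        len(out), int((groups == LOW).sum()), int((groups == HIGH).sum()),
    )
    return out


@dataclass(frozen=True)
class TimeDependentPerformance:
    """Confusion metrics of the high/low classification at a time horizon."""

    horizon_months: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_evaluable: int
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None


def _safe_ratio(num: int, denom: int, name: str) -> float:
    if denom == 0:
        warnings.warn(f"{name} undefined (empty denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / denom


def horizon_case_status(
    patients: pd.DataFrame, horizon_months: float
) -> pd.Series:
    """1 = case (event by horizon), 0 = control, NaN = censored early (excluded)."""
    if horizon_months <= 0:
        raise ValidationError("horizon must be positive")
    t = patients["time_months"].to_numpy(dtype=float)
    e = patients["event"].to_numpy(dtype=int)
    status = np.full(len(t), np.nan)
    status[(e == 1) & (t <= horizon_months)] = 1.0
    status[(t >= horizon_months) & ~((e == 1) & (t <= horizon_months))] = 0.0
    return pd.Series(status, index=patients.index, name="case")


def horizon_confusion(
    patients: pd.DataFrame,
    assignments: pd.DataFrame,
    horizon_months: float = 60.0,
) -> TimeDependentPerformance:
    """Sensitivity/specificity/PPV/NPV of high-risk status at a horizon."""
    merged = patients.merge(assignments[["patient_id", "group"]], on="patient_id")
    if len(merged) != len(patients):
        raise ValidationError("assignments do not cover the cohort")
    status = horizon_case_status(merged, horizon_months)
    evaluable = status.notna()
    case = status[evaluable].to_numpy() == 1.0
    high = (merged.loc[evaluable, "group"] == HIGH).to_numpy()
    tp = int((case & high).sum())
    fn = int((case & ~high).sum())
    fp = int((~case & high).sum())
    tn = int((~case & ~high).sum())
    n_excluded = int((~evaluable).sum())
    if n_excluded:
        logger.info("excluded %d patients censored event-free before %.0f months", n_excluded, horizon_months)
    return TimeDependentPerformance(
        horizon_months=horizon_months,
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        ppv=_safe_ratio(tp, tp + fp, "PPV"),
        npv=_safe_ratio(tn, tn + fn, "NPV"),
        n_evaluable=int(evaluable.sum()),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def score_auc(scores: Sequence[float], case_status: Sequence[int]) -> float:
    """AUC of the continuous score: Mann-Whitney probability of correct
    ranking of a random case/control pair, with half credit for ties."""
    y = np.asarray(case_status, dtype=int)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValidationError("scores and case_status must align")
    if len(np.unique(y)) < 2:
        raise ValidationError("both cases and controls are required for AUC")
    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class IncidenceCurve:
    """Right-continuous step estimate of cumulative metastasis incidence."""

    times: np.ndarray
    cumulative_incidence: np.ndarray

    def at(self, t: float) -> float:
        """Cumulative incidence at time t (right-continuous lookup)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.cumulative_incidence[idx])


def km_cumulative_incidence(patients: pd.DataFrame) -> IncidenceCurve:
    """1 minus the Kaplan-Meier survival of time-to-metastasis.

    All non-event exits are treated as right-censoring (no competing-risk
    decomposition).
    """
    if len(patients) == 0:
        raise ValidationError("empty patient table")
    t = patients["time_months"].to_numpy(dtype=float)
    if (t < 0).any():
        raise ValidationError("negative follow-up times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=patients["event"].to_numpy(dtype=int))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    incidence = 1.0 - sf.iloc[:, 0].to_numpy(dtype=float)
    return IncidenceCurve(times=times, cumulative_incidence=incidence)


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; (chi-square statistic with 1 df, p-value)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("both groups must be non-empty")
    if group_a["event"].sum() + group_b["event"].sum() == 0:
        warnings.warn("no events in either group; log-rank undefined", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(
        group_a["time_months"], group_b["time_months"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class GroupContrast:
    """High- versus low-risk effect estimate and rank test."""

    hazard_ratio: float
    ci95: tuple[float, float]
    logrank_statistic: float
    logrank_p: float
    flagged: bool = False


def group_hazard_ratio(
    patients: pd.DataFrame, assignments: pd.DataFrame
) -> GroupContrast:
    """Cox fit of the high-risk indicator, plus the log-rank comparison."""
    merged = patients.merge(assignments[["patient_id", "group"]], on="patient_id")
    merged = merged.assign(high_risk=(merged["group"] == HIGH).astype(int))
    low = merged[merged["high_risk"] == 0]
    high = merged[merged["high_risk"] == 1]
    stat, p = logrank(low, high)
    if low["event"].sum() == 0 or high["event"].sum() == 0:
        warnings.warn("one risk group has no events; hazard ratio near-separated", stacklevel=2)
    fit = univariate_ph(merged, "high_risk")
    return GroupContrast(
        hazard_ratio=fit.hazard_ratio,
        ci95=fit.ci95,
        logrank_statistic=stat,
        logrank_p=p,
        flagged=fit.flagged,
    )


def evaluate_model(
    patients: pd.DataFrame,
    model: RiskModel,
    horizon_months: float = 60.0,
    km_lookup_months: Sequence[float] = (12.0, 24.0, 60.0),
) -> dict:
    """Full evaluation block: groups, confusion, AUC, KM lookups, log-rank, HR."""
    assignments = classify(patients, model)
    perf = horizon_confusion(patients, assignments, horizon_months)
    status = horizon_case_status(
        patients.merge(assignments[["patient_id", "group"]], on="patient_id"),
        horizon_months,
    )
    evaluable = status.notna()
    auc = None
    scores = assignments["total_score"].to_numpy()
    if evaluable.any() and len(np.unique(status[evaluable])) == 2:
        auc = score_auc(scores[evaluable.to_numpy()], status[evaluable].to_numpy().astype(int))
    merged = patients.merge(assignments[["patient_id", "group"]], on="patient_id")
    low = merged[merged["group"] == LOW]
    high = merged[merged["group"] == HIGH]
    km = {}
    for label, grp in (("low", low), ("high", high), ("all", merged)):
        if len(grp) == 0:
            km[label] = {str(m): None for m in km_lookup_months}
            continue
        curve = km_cumulative_incidence(grp)
        km[label] = {str(m): curve.at(m) for m in km_lookup_months}
    contrast = None
    if len(low) and len(high):
        contrast = group_hazard_ratio(patients, assignments)
    return {
        "n": int(len(patients)),
        "n_events": int(patients["event"].sum()),
        "groups": {"low": int(len(low)), "high": int(len(high))},
        "events_by_group": {"low": int(low["event"].sum()), "high": int(high["event"].sum())},
        "horizon_months": horizon_months,
        "censoring_convention": "exclude-early-censored",
        "confusion": {
            "tp": perf.tp, "fp": perf.fp, "tn": perf.tn, "fn": perf.fn,
            "n_evaluable": perf.n_evaluable,
        },
        "metrics": {
            "sensitivity": perf.sensitivity,
            "specificity": perf.specificity,
            "ppv": perf.ppv,
            "npv": perf.npv,
            "auc": auc,
        },
        "km_cumulative_incidence": km,
        "group_contrast": None
        if contrast is None
        else {
            "hazard_ratio": contrast.hazard_ratio,
            "ci95": list(contrast.ci95),
            "logrank_statistic": contrast.logrank_statistic,
            "logrank_p": contrast.logrank_p,
            "flagged": contrast.flagged,
        },
    }
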