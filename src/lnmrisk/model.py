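"""Construction of the LNM risk score from time-to-event cohort data.

The pipeline mirrors a common clinical score-building recipe:

1. cross-tabulate each binary factor against the metastasis outcome
   (Pearson chi-square, or Fisher's exact test for sparse tables);
2. screen factors by single-covariate Cox proportional-hazards fits at a
   two-sided significance level alpha;
3. fit a joint Cox model to the screened factors (partial likelihood,
   Efron tie handling) and keep those that remain significant;
4. convert each retained covariate's Wald chi-square, (beta/se)^2, into an
   integer-friendly weight by dividing by the smallest retained chi-square
   and rounding half-away-from-zero to one decimal (so the least
   influential factor scores exactly 1.0);
5. total each patient's weights over the factors they carry, and pick the
   score cutoff whose above/below split maximizes the 2x2 Pearson
   chi-square over the midpoints between attained scores, reporting the
   Cochran-Armitage chi-square for linear trend alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LifelinesConvergence
from lifelines.exceptions import ConvergenceWarning as _LifelinesConvergenceWarning
from scipy import stats

from .errors import CollinearityError, ConvergenceError, ValidationError

#: the 19 binary clinicopathological / marker factors, in reporting order
FACTOR_NAMES = (
    "age_gt_51",
    "female",
    "hbsag_positive",
    "hcv_ab_positive",
    "afp_gt_20",
    "alt_gt_40",
    "ggt_gt_50",
    "cirrhosis",
    "child_pugh_b",
    "differentiation_iii_iv",
    "size_gt_5cm",
    "multiple_tumors",
    "no_encapsulation",
    "vascular_invasion",
    "bclc_b_c",
    "mir145_positive",
    "mir31_positive",
    "mir92a_positive",
    "mir10b_high",
)

#: the five factors of the published prediction score
MODEL_FACTORS = (
    "vascular_invasion",
    "bclc_b_c",
    "mir145_positive",
    "mir31_positive",
    "mir92a_positive",
)

#: sentinel hazard ratio for monotone-likelihood (separated) fits
SEPARATION_HR = math.inf


@dataclass(frozen=True)
class PatientRecord:
    """One subject: binary factor vector, follow-up, and LNM event flag."""

    patient_id: str
    factors: Mapping[str, int]
    time_months: float
    event: int
    cohort: str = "training"

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValidationError(f"time_months must be > 0, got {self.time_months}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0/1, got {self.event!r}")
        for name, value in self.factors.items():
            if value not in (0, 1):
                raise ValidationError(f"factor {name!r} must be 0/1, got {value!r}")


def patients_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Materialize records as the tabular cohort layout used throughout."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, **dict(r.factors)}
        row["time_months"] = r.time_months
        row["event"] = r.event
        row["cohort"] = r.cohort
        rows.append(row)
    if not rows:
        raise ValidationError("no patient records supplied")
    return pd.DataFrame(rows)


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    factor_cols = [c for c in df.columns if c not in ("patient_id", "time_months", "event", "cohort")]
    return [
        PatientRecord(
            patient_id=str(row["patient_id"]),
            factors={c: int(row[c]) for c in factor_cols},
            time_months=float(row["time_months"]),
            event=int(row["event"]),
            cohort=str(row.get("cohort", "training")),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# contingency analysis


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Factor-absent/present x event-free/event cell counts (a, b, c, d)."""

    a: int  # factor absent, no event
    b: int  # factor absent, event
    c: int  # factor present, no event
    d: int  # factor present, event

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValidationError("contingency cells must be non-negative")
        if self.total == 0:
            raise ValidationError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AssociationTestResult:
    statistic: float
    p_value: float
    method: str  # "chi-square" or "fisher"


def contingency_from_cohort(patients: pd.DataFrame, factor: str) -> ContingencyTable2x2:
    """Cross-tabulate one binary factor against the event indicator."""
    if len(patients) == 0:
        raise ValidationError("empty patient table")
    if factor not in patients.columns:
        raise ValidationError(f"unknown factor {factor!r}")
    x = patients[factor].to_numpy()
    e = patients["event"].to_numpy()
    return ContingencyTable2x2(
        a=int(((x == 0) & (e == 0)).sum()),
        b=int(((x == 0) & (e == 1)).sum()),
        c=int(((x == 1) & (e == 0)).sum()),
        d=int(((x == 1) & (e == 1)).sum()),
    )


def association_test(t: ContingencyTable2x2) -> AssociationTestResult:
    """Pearson chi-square (no continuity correction) or Fisher's exact test.

    Fisher is used when any expected cell count is below 5.  A table with a
    zero margin carries no information about association: the result is
    statistic 0, p = 1, with a warning rather than an exception.
    """
    table = t.as_array()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        warnings.warn("zero-margin contingency table; association undefined", stacklevel=2)
        return AssociationTestResult(statistic=0.0, p_value=1.0, method="chi-square")
    expected = np.outer(rows, cols) / t.total
    if (expected >= 5).all():
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return AssociationTestResult(statistic=float(stat), p_value=float(p), method="chi-square")
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationTestResult(statistic=float(odds_ratio), p_value=float(p), method="fisher")


# ---------------------------------------------------------------------------
# proportional-hazards fits


@dataclass(frozen=True)
class AssociationResult:
    """Single-factor effect estimate (univariate proportional hazards)."""

    factor: str
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float
    method: str = "univariate-PH"
    flagged: bool = False  # monotone likelihood / separation


@dataclass(frozen=True)
class CoxCovariateResult:
    """Per-covariate summary from a joint proportional-hazards fit."""

    factor: str
    beta: float
    se: float
    wald_chi2: float
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float


def _validate_survival_columns(patients: pd.DataFrame) -> None:
    for col in ("time_months", "event"):
        if col not in patients.columns:
            raise ValidationError(f"patient table lacks column {col!r}")
    if (patients["time_months"] <= 0).any():
        raise ValidationError("time_months must be positive")


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


#: Newton step sizes tried in turn; the default lifelines step can overshoot
#: on rare-factor covariates, a damped step is slower but stable
_COX_STEP_SIZES = (None, 0.5, 0.25, 0.1)


def _fit_cox(df: pd.DataFrame) -> tuple[CoxPHFitter | None, bool]:
    """Partial-likelihood fit with step-size fallback.

    Returns (fitter, flagged).  flagged=True marks a fit that only
    completed with convergence warnings (typically monotone likelihood);
    (None, True) means no step size produced finite estimates.
    """
    fallback = None
    for step in _COX_STEP_SIZES:
        cph = CoxPHFitter()
        kwargs = {} if step is None else {"fit_options": {"step_size": step}}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                cph.fit(df, duration_col="time_months", event_col="event", **kwargs)
            except (_LifelinesConvergence, np.linalg.LinAlgError, ValueError):
                continue
        params = cph.params_.to_numpy(dtype=float)
        ses = cph.standard_errors_.to_numpy(dtype=float)
        finite = np.isfinite(params).all() and np.isfinite(ses).all()
        warned = any(issubclass(w.category, _LifelinesConvergenceWarning) for w in caught)
        if finite and not warned:
            return cph, False
        if finite and fallback is None:
            fallback = cph
    if fallback is not None:
        return fallback, True
    return None, True


def univariate_ph(patients: pd.DataFrame, factor: str) -> AssociationResult:
    """Single-covariate Cox fit; Wald CI and p-value.

    Monotone likelihood (e.g. all events on one factor level) is reported
    as a flagged result with an infinite-hazard-ratio sentinel rather than
    raised, since a separated factor is still informative for screening.
    """
    _validate_survival_columns(patients)
    if len(patients) < 2:
        raise ValidationError("need at least 2 patients")
    if patients["event"].sum() == 0:
        raise ValidationError("no events in cohort")
    if factor not in patients.columns:
        raise ValidationError(f"unknown factor {factor!r}")
    levels = set(patients[factor].unique())
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} is constant across the cohort")

    df = patients[[factor, "time_months", "event"]].astype(float)
    cph, flagged = _fit_cox(df)
    if cph is None:
        warnings.warn(
            f"monotone likelihood for factor {factor!r}; reporting separation sentinel",
            stacklevel=2,
        )
        return AssociationResult(
            factor=factor,
            hazard_ratio=SEPARATION_HR,
            ci95=(0.0, SEPARATION_HR),
            p_value=float("nan"),
            flagged=True,
        )

    beta = float(cph.params_[factor])
    se = float(cph.standard_errors_[factor])
    if not (math.isfinite(beta) and math.isfinite(se)) or se > 1e3:
        flagged = True
    hr = _safe_exp(beta) if math.isfinite(beta) else SEPARATION_HR
    ci = (
        (_safe_exp(beta - 1.96 * se), _safe_exp(beta + 1.96 * se))
        if math.isfinite(se)
        else (0.0, SEPARATION_HR)
    )
    p = float(stats.chi2.sf((beta / se) ** 2, df=1)) if se > 0 else float("nan")
    return AssociationResult(factor=factor, hazard_ratio=hr, ci95=ci, p_value=p, flagged=flagged)


def screen_factors(
    patients: pd.DataFrame,
    factors: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[str]:
    """Return factors whose univariate Wald p-value is below alpha.

    Input order is preserved.  Factors whose univariate fit raises a
    validation error (constant column, etc.) are skipped with a warning.
    """
    if factors is None:
        factors = [f for f in FACTOR_NAMES if f in patients.columns]
    if not list(factors):
        raise ValidationError("no factors to screen")
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    kept = []
    for factor in factors:
        try:
            result = univariate_ph(patients, factor)
        except ValidationError as exc:
            warnings.warn(f"skipping factor {factor!r}: {exc}", stacklevel=2)
            continue
        if math.isfinite(result.p_value) and result.p_value < alpha:
            kept.append(factor)
    return kept


def _check_collinearity(patients: pd.DataFrame, factors: Sequence[str]) -> None:
    X = patients[list(factors)].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    corr = np.corrcoef(Xc, rowvar=False)
    for i in range(len(factors)):
        for j in range(i + 1, len(factors)):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise CollinearityError(
                    f"factors {factors[i]!r} and {factors[j]!r} are collinear"
                )
    if np.linalg.matrix_rank(Xc) < len(factors):
        raise CollinearityError(f"design matrix for {list(factors)} is rank-deficient")


def fit_multivariate_ph(
    patients: pd.DataFrame,
    factors: Sequence[str],
    tie_method: str = "efron",
) -> list[CoxCovariateResult]:
    """Joint Cox proportional-hazards fit of the given binary factors.

    Returns one result per covariate with the Wald chi-square (beta/se)^2
    that feeds the weight derivation.  Only the Efron tie approximation is
    supported.
    """
    factors = list(factors)
    if not factors:
        raise ValidationError("no factors supplied")
    if tie_method != "efron":
        raise ValidationError(f"unsupported tie method {tie_method!r}; only 'efron' is available")
    _validate_survival_columns(patients)
    n_events = int(patients["event"].sum())
    if n_events < len(factors):
        raise ValidationError(
            f"{n_events} events cannot support {len(factors)} covariates"
        )
    for factor in factors:
        if factor not in patients.columns:
            raise ValidationError(f"unknown factor {factor!r}")
        if patients[factor].nunique() < 2:
            raise ValidationError(f"factor {factor!r} is constant across the cohort")
    _check_collinearity(patients, factors)

    df = patients[factors + ["time_months", "event"]].astype(float)
    cph, flagged = _fit_cox(df)
    if cph is None:
        raise ConvergenceError(
            f"joint fit of {list(factors)} failed to converge at any step size"
        )
    if flagged:
        warnings.warn(
            f"joint fit of {list(factors)} converged with warnings; estimates may be unstable",
            stacklevel=2,
        )

    results = []
    for factor in factors:
        beta = float(cph.params_[factor])
        se = float(cph.standard_errors_[factor])
        wald = (beta / se) ** 2
        results.append(
            CoxCovariateResult(
                factor=factor,
                beta=beta,
                se=se,
                wald_chi2=wald,
                hazard_ratio=_safe_exp(beta),
                ci95=(_safe_exp(beta - 1.96 * se), _safe_exp(beta + 1.96 * se)),
                p_value=float(stats.chi2.sf(wald, df=1)),
            )
        )
    return results


# ---------------------------------------------------------------------------
# score table and cutoff


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ScoreTable:
    """Factor -> one-decimal weight map; the least influential factor weighs 1.0."""

    weights: Mapping[str, float]
    reference_chi2: float

    @property
    def max_score(self) -> float:
        return round(sum(self.weights.values()), 10)


def derive_weights(
    results: Sequence[CoxCovariateResult] | Mapping[str, float],
) -> ScoreTable:
    """Divide each covariate's Wald chi-square by the smallest one.

    Accepts either joint-fit results or a plain factor -> chi-square map
    (so printed chi-square columns can be fed in directly).  Ratios are
    rounded half-away-from-zero to one decimal; the minimum-chi-square
    factor therefore gets weight exactly 1.0.
    """
    if isinstance(results, Mapping):
        chi2 = dict(results)
    else:
        chi2 = {r.factor: r.wald_chi2 for r in results}
    if not chi2:
        raise ValidationError("no covariate results supplied")
    for factor, value in chi2.items():
        if not (math.isfinite(value) and value > 0):
            raise ValidationError(f"chi-square for {factor!r} must be finite and > 0, got {value!r}")
    reference = min(chi2.values())
    weights = {f: _round_half_away(v / reference, 1) for f, v in chi2.items()}
    return ScoreTable(weights=weights, reference_chi2=reference)


def total_score(patient: Mapping[str, object] | pd.Series, table: ScoreTable) -> float:
    """Aggregate the weights of the factors the patient carries."""
    score = 0.0
    for factor, weight in table.weights.items():
        if factor not in patient:
            raise ValidationError(f"patient lacks factor {factor!r}")
        value = patient[factor]
        if value not in (0, 1):
            raise ValidationError(f"factor {factor!r} must be 0/1, got {value!r}")
        score += weight * int(value)
    return round(score, 10)


def total_scores(patients: pd.DataFrame, table: ScoreTable) -> pd.Series:
    """Vectorized total score for every row of a cohort table."""
    missing = [f for f in table.weights if f not in patients.columns]
    if missing:
        raise ValidationError(f"patient table lacks factors: {missing}")
    X = patients[list(table.weights)].to_numpy(dtype=float)
    w = np.array([table.weights[f] for f in table.weights])
    return pd.Series(np.round(X @ w, 10), index=patients.index, name="total_score")


def _pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    # closed form n(ad-bc)^2 / (r1 r2 c1 c2); 0 on zero margins
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def cochran_armitage_trend(
    category_scores: Sequence[float],
    n_per_category: Sequence[int],
    events_per_category: Sequence[int],
) -> float:
    """Chi-square (1 df) for linear trend in event proportion across ordered categories."""
    t = np.asarray(category_scores, dtype=float)
    n = np.asarray(n_per_category, dtype=float)
    d = np.asarray(events_per_category, dtype=float)
    N = n.sum()
    D = d.sum()
    if N == 0 or D == 0 or D == N:
        return 0.0
    num = (t @ d - D * (t @ n) / N) ** 2
    var = D * (N - D) / N**2 * ((n @ t**2) - (t @ n) ** 2 / N)
    if var <= 0:
        return 0.0
    return float(num / var)


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    chi2: float  # 2x2 Pearson chi-square at the selected cutoff
    trend_chi2: float  # Cochran-Armitage statistic over all score categories
    candidates: tuple[tuple[float, float], ...] = field(repr=False, default=())


def select_cutoff(scores: Sequence[float], outcomes: Sequence[int]) -> CutoffResult:
    """Pick the risk-score cutoff with the best above/below event separation.

    Candidates are the midpoints between consecutive distinct attained
    scores; for each, the 2x2 (score > cutoff x event) Pearson chi-square
    is computed and the maximizer returned, ties broken toward the smaller
    cutoff.  The chi-square for linear trend over all attained score
    levels is reported alongside as a diagnostic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and outcomes must be 1-d and equal length")
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValidationError("all scores identical; no cutoff exists")
    if len(np.unique(y)) < 2:
        raise ValidationError("all outcomes identical; separation undefined")

    candidates = []
    best = None
    for cut in np.round((distinct[:-1] + distinct[1:]) / 2.0, 10):
        high = s > cut
        a = int((~high & (y == 0)).sum())
        b = int((~high & (y == 1)).sum())
        c = int((high & (y == 0)).sum())
        d = int((high & (y == 1)).sum())
        chi2 = _pearson_chi2_2x2(a, b, c, d)
        candidates.append((float(cut), chi2))
        if best is None or chi2 > best[1] + 1e-12:
            best = (float(cut), chi2)

    n_per = [int((s == v).sum()) for v in distinct]
    d_per = [int(y[s == v].sum()) for v in distinct]
    trend = cochran_armitage_trend(distinct, n_per, d_per)
    return CutoffResult(cutoff=best[0], chi2=best[1], trend_chi2=trend, candidates=tuple(candidates))


# ---------------------------------------------------------------------------
# end-to-end model construction


@dataclass(frozen=True)
class RiskModel:
    """Fitted score table plus the selected high/low-risk cutoff."""

    score_table: ScoreTable
    cutoff: float | None
    trend_statistic_at_cutoff: float | None = None
    cochran_armitage_trend: float | None = None
    screened_factors: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "weights": dict(self.score_table.weights),
            "reference_chi2": self.score_table.reference_chi2,
            "cutoff": self.cutoff,
            "trend_statistic_at_cutoff": self.trend_statistic_at_cutoff,
            "cochran_armitage_trend": self.cochran_armitage_trend,
            "screened_factors": list(self.screened_factors),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RiskModel":
        return cls(
            score_table=ScoreTable(
                weights=dict(payload["weights"]),
                reference_chi2=float(payload["reference_chi2"]),
            ),
            cutoff=None if payload.get("cutoff") is None else float(payload["cutoff"]),
            trend_statistic_at_cutoff=payload.get("trend_statistic_at_cutoff"),
            cochran_armitage_trend=payload.get("cochran_armitage_trend"),
            screened_factors=tuple(payload.get("screened_factors", ())),
        )


def build_model(
    patients: pd.DataFrame,
    factors: Sequence[str] | None = None,
    alpha: float = 0.05,
    tie_method: str = "efron",
) -> RiskModel:
    """Screen -> joint fit -> prune -> weights -> cutoff, on one cohort.

    Covariates that lose significance in the joint fit are dropped and the
    model refit once on the survivors before weights are derived, so the
    score only contains independently predictive factors.
    """
    screened = screen_factors(patients, factors, alpha=alpha)
    if len(screened) < 1:
        raise ValidationError("no factor passed univariate screening")
    results = fit_multivariate_ph(patients, screened, tie_method=tie_method)
    retained = [r.factor for r in results if r.p_value < alpha]
    if not retained:
        raise ValidationError("no factor remained significant in the joint fit")
    if retained != [r.factor for r in results]:
        results = fit_multivariate_ph(patients, retained, tie_method=tie_method)
    table = derive_weights(results)
    scores = total_scores(patients, table)
    cut = select_cutoff(scores.to_numpy(), patients["event"].to_numpy())
    return RiskModel(
        score_table=table,
        cutoff=cut.cutoff,
        trend_statistic_at_cutoff=cut.chi2,
        cochran_armitage_trend=cut.trend_chi2,
        screened_factors=tuple(screened),
    )
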