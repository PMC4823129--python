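"""Semi-quantitative ISH marker scoring and qRT-PCR fold-change computation.

Four miRNA markers are scored on tissue cores, each with its own published
scoring system, and dichotomized into the binary calls consumed by the risk
model:

* ``miR-145`` and ``miR-31`` use an additive system: chromogenic intensity
  (0 = none, 1 = weak, 2 = intermediate, 3 = strong) plus a percentage
  category (0 = 0 %, 1 = <30 %, 2 = >30 % of cells), giving a final score
  of 0-5.  miR-145 is positive when the final score exceeds 4; miR-31 when
  it exceeds 3.
* ``miR-92a`` uses a four-tier intensity-only score 0-3 and is positive
  when the final score exceeds 0.5 (a threshold that is meaningful after
  two-rater averaging).
* ``miR-10b`` uses the fraction of stained cells (0-100 %) and is called
  high-expression when at least 20 % of cells stain.

Scores from independent raters (two pathologists in the intended workflow,
any number here) are averaged on the final-score scale before the threshold
is applied; averaged scores are compared to thresholds without rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: canonical marker identifiers
MIR145 = "mir145"
MIR31 = "mir31"
MIR92A = "mir92a"
MIR10B = "mir10b"

ADDITIVE_MARKERS = (MIR145, MIR31)
INTENSITY_MARKERS = (MIR92A,)
PERCENT_MARKERS = (MIR10B,)
MARKERS = ADDITIVE_MARKERS + INTENSITY_MARKERS + PERCENT_MARKERS

#: final-score range attainable under each marker's scoring system
SCORE_RANGES: Mapping[str, tuple[float, float]] = {
    MIR145: (0.0, 5.0),
    MIR31: (0.0, 5.0),
    MIR92A: (0.0, 3.0),
    MIR10B: (0.0, 100.0),
}

#: positive iff final score strictly exceeds this value (additive / intensity markers)
POSITIVE_ABOVE: Mapping[str, float] = {MIR145: 4.0, MIR31: 3.0, MIR92A: 0.5}

#: miR-10b is high-expression iff percent stained is >= this value (inclusive)
HIGH_PERCENT_AT_LEAST = 20.0

#: label pairs (negative-side, positive-side) per marker
CALL_LABELS: Mapping[str, tuple[str, str]] = {
    MIR145: ("negative", "positive"),
    MIR31: ("negative", "positive"),
    MIR92A: ("negative", "positive"),
    MIR10B: ("low", "high"),
}


def normalize_marker(name: str) -> str:
    """Map marker spellings such as ``miR-145`` or ``MIR_92A`` to canonical ids."""
    if not isinstance(name, str):
        raise ValidationError(f"marker must be a string, got {type(name).__name__}")
    canonical = name.strip().lower().replace("-", "").replace("_", "")
    if canonical not in MARKERS:
        raise ValidationError(
            f"unknown marker {name!r}; expected one of {', '.join(MARKERS)}"
        )
    return canonical


@dataclass(frozen=True)
class IshReading:
    """One rater's reading of one tissue core for one marker.

    Exactly the fields relevant to the marker's scoring system must be set:
    ``intensity`` and ``percentage_category`` for the additive markers,
    ``intensity`` alone for miR-92a, and ``percent_stained`` for miR-10b.
    """

    marker: str
    rater_id: str
    intensity: int | None = None
    percentage_category: int | None = None
    percent_stained: float | None = None
    core_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", normalize_marker(self.marker))

    def final_score(self) -> float:
        """This rater's final score on the marker's scoring scale."""
        m = self.marker
        if m in ADDITIVE_MARKERS:
            if self.intensity is None or self.percentage_category is None:
                raise ValidationError(
                    f"{m} requires intensity and percentage_category"
                )
            return float(score_additive_marker(self.intensity, self.percentage_category))
        if m in INTENSITY_MARKERS:
            if self.intensity is None:
                raise ValidationError(f"{m} requires intensity")
            _check_range("intensity", self.intensity, 0, 3, integral=True)
            return float(self.intensity)
        # percent-stained marker
        if self.percent_stained is None:
            raise ValidationError(f"{m} requires percent_stained")
        _check_range("percent_stained", self.percent_stained, 0.0, 100.0)
        return float(self.percent_stained)


@dataclass(frozen=True)
class MarkerCall:
    """Dichotomized marker status after rater averaging."""

    marker: str
    final_score: float
    call: str

    @property
    def positive(self) -> bool:
        return self.call == CALL_LABELS[self.marker][1]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct quadruple for relative expression of a target miRNA.

    The target is normalized to an endogenous reference (U6 snRNA in the
    intended assay) in both the sample of interest and a calibrator sample.
    """

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for field in (
            "ct_target_sample",
            "ct_reference_sample",
            "ct_target_calibrator",
            "ct_reference_calibrator",
        ):
            value = getattr(self, field)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{field} must be finite and > 0, got {value!r}")


def _check_range(field, value, lo, hi, integral=False):
    if integral:
        if not float(value).is_integer():
            raise ValidationError(f"{field} must be an integer, got {value!r}")
    if not (lo <= value <= hi):
        raise ValidationError(f"{field} must be in [{lo}, {hi}], got {value!r}")


def score_additive_marker(intensity: int, percentage_category: int) -> int:
    """Final score = intensity (0-3) + percentage category (0-2), range 0-5."""
    _check_range("intensity", intensity, 0, 3, integral=True)
    _check_range("percentage_category", percentage_category, 0, 2, integral=True)
    return int(intensity) + int(percentage_category)


def call_marker(marker: str, final_score: float) -> str:
    """Dichotomize a (possibly rater-averaged, non-integer) final score.

    The boundary falls on the negative/low side for the three expression
    markers (score equal to the threshold is negative) and on the high side
    for miR-10b (exactly 20 % stained is high).
    """
    marker = normalize_marker(marker)
    lo, hi = SCORE_RANGES[marker]
    if not (lo <= final_score <= hi):
        raise ValidationError(
            f"final_score {final_score!r} outside {marker} range [{lo}, {hi}]"
        )
    negative_label, positive_label = CALL_LABELS[marker]
    if marker == MIR10B:
        return positive_label if final_score >= HIGH_PERCENT_AT_LEAST else negative_label
    return positive_label if final_score > POSITIVE_ABOVE[marker] else negative_label


def aggregate_raters(readings: Sequence[IshReading]) -> MarkerCall:
    """Average the per-rater final scores and dichotomize the mean.

    All readings must concern the same marker.  Readings from multiple
    cores of the same tumor are averaged together with rater replicates
    (logged, since core-level disagreement has no separate resolution rule).
    """
    readings = list(readings)
    if not readings:
        raise ValidationError("aggregate_raters requires at least one reading")
    markers = {r.marker for r in readings}
    if len(markers) > 1:
        raise ValidationError(f"mixed markers in aggregate_raters: {sorted(markers)}")
    cores = {r.core_id for r in readings if r.core_id is not None}
    if len(cores) > 1:
        logger.info(
            "averaging %d readings across %d cores for %s",
            len(readings), len(cores), readings[0].marker,
        )
    mean_score = sum(r.final_score() for r in readings) / len(readings)
    marker = readings[0].marker
    return MarkerCall(marker=marker, final_score=mean_score, call=call_marker(marker, mean_score))


def fold_change_ddct(m: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) within each of sample and calibrator;
    ddCt is the sample dCt minus the calibrator dCt; relative expression is
    2 raised to -ddCt (1.0 means no change versus the calibrator).
    """
    dct_sample = m.ct_target_sample - m.ct_reference_sample
    dct_calibrator = m.ct_target_calibrator - m.ct_reference_calibrator
    return 2.0 ** (-(dct_sample - dct_calibrator))


# ---------------------------------------------------------------------------
# tabular interface

READINGS_COLUMNS = (
    "patient_id",
    "core_id",
    "marker",
    "rater_id",
    "intensity",
    "percentage_category",
    "percent_stained",
)


def read_readings_table(
    path, delimiter: str = "\t", missing: str = ""
) -> pd.DataFrame:
    """Read a delimited ISH readings table (one row per rater x core x marker)."""
    df = pd.read_csv(
        path, sep=delimiter, comment="#", dtype=str, keep_default_na=False
    )
    missing_cols = set(READINGS_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"readings table missing columns: {sorted(missing_cols)}")
    df = df.replace(missing, pd.NA)
    for col in ("intensity", "percentage_category", "percent_stained"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["marker"] = df["marker"].map(normalize_marker)
    return df


def _reading_from_row(row) -> IshReading:
    def opt_int(v):
        return None if pd.isna(v) else int(v)

    return IshReading(
        marker=row["marker"],
        rater_id=str(row["rater_id"]),
        core_id=None if pd.isna(row.get("core_id")) else str(row["core_id"]),
        intensity=opt_int(row["intensity"]),
        percentage_category=opt_int(row["percentage_category"]),
        percent_stained=None if pd.isna(row["percent_stained"]) else float(row["percent_stained"]),
    )


def call_markers_table(readings: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a readings table into one marker call per (patient, marker).

    Returns a frame with columns patient_id, marker, final_score, call.
    """
    records = []
    for (patient_id, marker), group in readings.groupby(
        ["patient_id", "marker"], sort=True
    ):
        call = aggregate_raters([_reading_from_row(r) for _, r in group.iterrows()])
        records.append(
            {
                "patient_id": patient_id,
                "marker": marker,
                "final_score": call.final_score,
                "call": call.call,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["patient_id", "marker", "final_score", "call"]
    )


def write_marker_calls(calls: pd.DataFrame, path, delimiter: str = "\t") -> None:
    calls.to_csv(path, sep=delimiter, index=False)
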