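"""Tabular and JSON serialization: patient tables, model artifacts, reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ValidationError
from .model import FACTOR_NAMES, RiskModel

REQUIRED_COLUMNS = ("patient_id", "time_months", "event")


@dataclass
class PipelineConfig:
    """Run-level knobs shared by the CLI subcommands."""

    alpha: float = 0.05
    horizon_months: float = 60.0
    tie_method: str = "efron"
    cutoff_rule: str = "max-chi2-midpoint"
    km_lookup_months: tuple[float, ...] = (12.0, 24.0, 60.0)
    seed: int = 0
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.horizon_months <= 0:
            raise ValidationError("horizon_months must be positive")
        if self.cutoff_rule != "max-chi2-midpoint":
            raise ValidationError(f"unknown cutoff rule {self.cutoff_rule!r}")
        self.km_lookup_months = tuple(float(m) for m in self.km_lookup_months)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Read YAML/JSON config; keyword overrides win over file values."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        if not isinstance(values, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)


def read_patient_table(
    path: str | Path, delimiter: str = "\t", require_outcome: bool = True
) -> pd.DataFrame:
    """Read a delimited patient table; lines starting with '#' are comments.

    With ``require_outcome=False`` the follow-up columns are optional, so
    factor-only tables can be scored against an existing model.
    """
    df = pd.read_csv(path, sep=delimiter, comment="#")
    required = REQUIRED_COLUMNS if require_outcome else ("patient_id",)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"patient table missing columns: {sorted(missing)}")
    factor_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c != "cohort"
    ]
    check_cols = factor_cols + (["event"] if "event" in df.columns else [])
    for col in check_cols:
        values = set(pd.unique(df[col]))
        if not values <= {0, 1}:
            raise ValidationError(f"column {col!r} must be 0/1 coded, found {sorted(values)[:5]}")
    if "time_months" in df.columns and (df["time_months"] <= 0).any():
        raise ValidationError("time_months must be positive")
    return df


def write_patient_table(
    df: pd.DataFrame,
    path: str | Path,
    delimiter: str = "\t",
    header_comment: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=delimiter, index=False)


def _provenance(config: PipelineConfig | None, seed: int | None) -> dict:
    from . import __version__

    return {
        "version": __version__,
        "seed": seed,
        "config_hash": None if config is None else config.config_hash(),
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def write_model_json(
    model: RiskModel,
    path: str | Path,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> None:
    payload = model.to_dict()
    payload["provenance"] = _provenance(config, seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model_json(path: str | Path) -> RiskModel:
    with open(path) as fh:
        payload = json.load(fh)
    return RiskModel.from_dict(payload)


def write_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
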