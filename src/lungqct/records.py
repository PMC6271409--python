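"""Per-patient records joining CT indexes, clinical covariates and outcome.

A :class:`PatientRecord` is the tabular unit the survival module consumes:
baseline histogram indexes, pulmonary function (percent of predicted), the
GAP point score (consumed as given, never computed here), follow-up time in
days and the vital-status flag.  Optional ``followup_*`` fields hold the
12 +/- 3 month re-examination when one exists.

Records convert losslessly to and from a flat pandas row; missing values
stay missing (NaN) and are never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import pandas as pd

#: baseline columns required in every cohort table
REQUIRED_COLUMNS = ("patient_id", "followup_days", "deceased")

#: CT index columns, in canonical order
INDEX_COLUMNS = ("kurtosis", "skewness", "mld", "haa_pct", "fa_pct")

#: clinical columns, optional but with fixed names
CLINICAL_COLUMNS = (
    "age_years", "sex", "smoking_status",
    "fvc_pct_pred", "dlco_pct_pred", "gap_points",
)

#: variables compared between baseline and the follow-up visit
VISIT_COMPARISON_FAMILY = (
    "kurtosis", "skewness", "mld", "haa_pct", "fa_pct",
    "fvc_pct_pred", "dlco_pct_pred", "gap_points",
)

#: follow-up visit columns carry this prefix in flat tables
FOLLOWUP_PREFIX = "fu_"


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class PatientRecord:
    """One patient: baseline indexes + clinical covariates + outcome."""

    patient_id: str
    followup_days: float
    deceased: int
    age_years: float = float("nan")
    sex: Optional[str] = None
    smoking_status: Optional[str] = None
    fvc_pct_pred: float = float("nan")
    dlco_pct_pred: float = float("nan")
    gap_points: float = float("nan")
    kurtosis: float = float("nan")
    skewness: float = float("nan")
    mld: float = float("nan")
    haa_pct: float = float("nan")
    fa_pct: float = float("nan")
    lung_volume_ml: float = float("nan")
    followup: dict = field(default_factory=dict)  # fu_* visit values, unprefixed keys

    def __post_init__(self) -> None:
        if self.followup_days < 0:
            raise ValueError(
                f"patient {self.patient_id!r}: followup_days={self.followup_days} < 0"
            )
        if self.deceased not in (0, 1):
            raise ValueError(
                f"patient {self.patient_id!r}: deceased={self.deceased!r} not in {{0, 1}}"
            )
        for name in ("fvc_pct_pred", "dlco_pct_pred"):
            v = getattr(self, name)
            if not _isnan(v) and not (0.0 < v < 200.0):
                raise ValueError(f"patient {self.patient_id!r}: {name}={v} outside (0, 200)")

    def to_row(self) -> dict:
        row = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "followup"}
        for key, val in self.followup.items():
            row[FOLLOWUP_PREFIX + key] = val
        return row

    @classmethod
    def from_row(cls, row: dict) -> "PatientRecord":
        known = {f.name for f in fields(cls)} - {"followup"}
        base = {k: v for k, v in row.items() if k in known}
        fu = {
            k[len(FOLLOWUP_PREFIX):]: v
            for k, v in row.items()
            if k.startswith(FOLLOWUP_PREFIX) and not _isnan(v)
        }
        base["deceased"] = int(base["deceased"])
        base["followup_days"] = float(base["followup_days"])
        return cls(followup=fu, **base)


def records_to_frame(records: Iterable[PatientRecord] | pd.DataFrame) -> pd.DataFrame:
    """Flatten records to a DataFrame; passes a DataFrame through untouched."""
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if not records:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return pd.DataFrame([r.to_row() for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    return [PatientRecord.from_row(row.to_dict()) for _, row in frame.iterrows()]
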