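"""Analysis-ready patient cohorts.

A cohort row joins the averaged subjective indexes (MID, SPR, SPRL, SPRR)
with two objective severity scores — PIM2, the Pediatric Index of Mortality
2 death-risk percentage computed at admission, and TISS28, the Therapeutic
Intervention Scoring System 28 workload score from the first 24 h — and the
PICU-discharge outcome (0 = survivor, 1 = nonsurvivor).  Both scores are
consumed as given; this package never computes them from raw items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fuzzy import (
    INDEX_COLUMNS,
    FuzzyIndexes,
    ValidationError,
    average_by_patient,
    read_evaluations,
)

logger = logging.getLogger(__name__)

_TOL = 1e-9

CENTERS = ("oviedo", "riga")
PREDICTOR_COLUMNS = ("MID", "SPR", "SPRL", "SPRR", "PIM2", "TISS28")

#: required columns of the patients CSV
PATIENT_COLUMNS = ("patient_id", "center", "outcome", "pim2", "tiss28")
OPTIONAL_PATIENT_COLUMNS = ("age_years", "sex", "diagnosis_group")

#: canonical columns of an analysis-ready cohort frame
COHORT_COLUMNS = (
    "patient_id",
    "center",
    "outcome",
    "MID",
    "SPR",
    "SPRL",
    "SPRR",
    "PIM2",
    "TISS28",
)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    center: str
    outcome: int
    fuzzy: FuzzyIndexes
    pim2: float
    tiss28: float
    age_years: float | None = None
    sex: str | None = None
    diagnosis_group: str | None = None


@dataclass
class Cohort:
    """Validated patient table; ``data`` holds the canonical columns."""

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort missing columns {missing}")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"duplicated patient_id {dup!r}")
        if not df["outcome"].isin([0, 1]).all():
            bad = df.loc[~df["outcome"].isin([0, 1]), "outcome"].iloc[0]
            raise ValidationError(f"outcome must be 0 or 1, found {bad!r}")
        _check_range(df, "PIM2", 0, 100)
        _check_range(df, "MID", 0, 100)
        for col in ("SPR", "SPRL", "SPRR", "TISS28"):
            _check_range(df, col, 0, np.inf)
        viol = (
            (df["MID"] - df["SPR"] < -_TOL)
            | (df["MID"] + df["SPR"] > 100 + _TOL)
            | (df["MID"] - df["SPR"] - df["SPRL"] < -_TOL)
            | (df["MID"] + df["SPR"] + df["SPRR"] > 100 + _TOL)
        )
        if viol.any():
            pid = df.loc[viol, "patient_id"].iloc[0]
            raise ValidationError(
                f"patient {pid!r}: fuzzy indexes leave the [0, 100] scale"
            )
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_deaths(self) -> int:
        return int(self.data["outcome"].sum())

    @property
    def outcomes(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=int)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    center=row.center,
                    outcome=int(row.outcome),
                    fuzzy=FuzzyIndexes(row.MID, row.SPR, row.SPRL, row.SPRR),
                    pim2=row.PIM2,
                    tiss28=row.TISS28,
                    age_years=getattr(row, "age_years", None),
                    sex=getattr(row, "sex", None),
                    diagnosis_group=getattr(row, "diagnosis_group", None),
                )
            )
        return out

    def subset(self, mask: np.ndarray, label: str | None = None) -> "Cohort":
        return Cohort(self.data.loc[np.asarray(mask)].copy(), label or self.label)


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float) -> None:
    vals = df[col]
    bad = vals.isna() | (vals < lo - _TOL) | (vals > hi + _TOL)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"column {col!r}, row {row}: value {vals.iloc[row]!r} outside "
            f"[{lo}, {hi}]"
        )


def load_cohort(
    patients_csv: str | Path,
    evaluations_csv: str | Path,
    label: str = "",
    repair_nesting: bool = False,
) -> Cohort:
    """Join the patient table with per-patient averaged fuzzy indexes.

    Patients with zero evaluations are excluded with a logged count.
    """
    patients = pd.read_csv(patients_csv)
    src = str(patients_csv)
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise ValidationError(f"{src}: missing columns {missing}")
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"{src}: duplicated patient_id {dup!r}")
    outcome = pd.to_numeric(patients["outcome"], errors="coerce")
    if not outcome.isin([0, 1]).all():
        row = int(np.flatnonzero(~outcome.isin([0, 1]).to_numpy())[0])
        raise ValidationError(
            f"{src}: column 'outcome', row {row}: must be 0 (survivor) or 1 "
            f"(nonsurvivor), found {patients['outcome'].iloc[row]!r}"
        )
    patients["outcome"] = outcome.astype(int)
    _check_range(patients.rename(columns={"pim2": "PIM2"}), "PIM2", 0, 100)
    _check_range(patients.rename(columns={"tiss28": "TISS28"}), "TISS28", 0, np.inf)

    evals = read_evaluations(evaluations_csv, repair_nesting=repair_nesting)
    averaged = average_by_patient(evals)

    merged = patients.merge(averaged, on="patient_id", how="inner")
    dropped = len(patients) - len(merged)
    if dropped:
        logger.warning(
            "%s: excluded %d patient(s) with no evaluations", src, dropped
        )
    merged = merged.rename(columns={"pim2": "PIM2", "tiss28": "TISS28"})
    keep = [c for c in (*COHORT_COLUMNS, *OPTIONAL_PATIENT_COLUMNS) if c in merged.columns]
    return Cohort(merged[keep], label=label)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the analysis-ready cohort as a single flat CSV."""
    cohort.data.to_csv(path, index=False)


def read_cohort(path: str | Path, label: str = "") -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    return Cohort(pd.read_csv(path, float_precision="round_trip"), label=label)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-center and overall counts plus mean/SD of MID, PIM2, TISS28.

    Means and SDs (n-1 denominator) are reported overall and within each
    outcome class, mirroring the usual two-center descriptive table.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    rows = []
    groups = [("total", cohort.data)]
    for center, sub in cohort.data.groupby("center", sort=True):
        groups.append((str(center), sub))
    for name, df in groups:
        base = {
            "cohort": name,
            "n": len(df),
            "deaths": int(df["outcome"].sum()),
        }
        for var in ("MID", "PIM2", "TISS28"):
            for grp, sub in (
                ("all", df),
                ("survivors", df[df["outcome"] == 0]),
                ("nonsurvivors", df[df["outcome"] == 1]),
            ):
                rows.append(
                    {
                        **base,
                        "variable": var,
                        "group": grp,
                        "mean": sub[var].mean(),
                        "sd": sub[var].std(ddof=1),
                    }
                )
    return pd.DataFrame(rows)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)
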