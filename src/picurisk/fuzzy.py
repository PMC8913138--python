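"""Trapezoidal fuzzy elicitation of subjective mortality risk.

Bedside staff express a patient's risk of death as two nested percentage
ranges on [0, 100]: a *short range* (the most plausible interval, the 1-cut
of the trapezoid) and a *long range* (the almost-certain interval, the
0-cut / support).  The two ranges define a trapezoidal membership function
which is summarised by four indexes:

=====  ==============================================================
MID    midpoint of the short range
SPR    radius (half-width) of the short range
SPRL   distance from the long-range infimum to the short-range infimum
SPRR   distance from the short-range supremum to the long-range supremum
=====  ==============================================================

All four indexes live on the 0-100 percent scale.  Multiple evaluations of
the same patient are combined by the componentwise arithmetic mean of the
indexes, which coincides with the pointwise (Minkowski) mean of the
trapezoids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_TOL = 1e-9

RATER_ROLES = ("physician", "nurse", "unknown")

EVALUATION_COLUMNS = (
    "patient_id",
    "rater_role",
    "short_lo",
    "short_hi",
    "long_lo",
    "long_hi",
)

INDEX_COLUMNS = ("MID", "SPR", "SPRL", "SPRR")


class ValidationError(ValueError):
    """Raised when an evaluation or index set violates its invariants."""


@dataclass(frozen=True)
class TrapezoidEvaluation:
    """One rater's short + long risk ranges for one patient (percent)."""

    patient_id: str
    short_lo: float
    short_hi: float
    long_lo: float
    long_hi: float
    rater_role: str = "unknown"

    def __post_init__(self) -> None:
        for field in ("short_lo", "short_hi", "long_lo", "long_hi"):
            v = getattr(self, field)
            if not np.isfinite(v) or v < -_TOL or v > 100 + _TOL:
                raise ValidationError(
                    f"{field}={v!r} outside the [0, 100] percent scale"
                )
        if self.short_lo > self.short_hi + _TOL:
            raise ValidationError(
                f"short_lo={self.short_lo} exceeds short_hi={self.short_hi}"
            )
        if self.long_lo > self.short_lo + _TOL:
            raise ValidationError(
                f"long_lo={self.long_lo} exceeds short_lo={self.short_lo}: "
                "short range must be nested in the long range"
            )
        if self.short_hi > self.long_hi + _TOL:
            raise ValidationError(
                f"short_hi={self.short_hi} exceeds long_hi={self.long_hi}: "
                "short range must be nested in the long range"
            )


@dataclass(frozen=True)
class FuzzyIndexes:
    """Four-index parameterization (MID, SPR, SPRL, SPRR) of a trapezoid."""

    mid: float
    spr: float
    sprl: float
    sprr: float

    def __post_init__(self) -> None:
        for field in ("spr", "sprl", "sprr"):
            if getattr(self, field) < -_TOL:
                raise ValidationError(f"{field} must be nonnegative")
        if not -_TOL <= self.mid <= 100 + _TOL:
            raise ValidationError(f"mid={self.mid} outside [0, 100]")
        if self.mid - self.spr < -_TOL:
            raise ValidationError("mid - spr < 0: short range leaves [0, 100]")
        if self.mid + self.spr > 100 + _TOL:
            raise ValidationError("mid + spr > 100: short range leaves [0, 100]")
        if self.mid - self.spr - self.sprl < -_TOL:
            raise ValidationError("mid - spr - sprl < 0: long range leaves [0, 100]")
        if self.mid + self.spr + self.sprr > 100 + _TOL:
            raise ValidationError("mid + spr + sprr > 100: long range leaves [0, 100]")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mid, self.spr, self.sprl, self.sprr)


def parameterize(e: TrapezoidEvaluation) -> FuzzyIndexes:
    """Map a trapezoid evaluation to its (MID, SPR, SPRL, SPRR) indexes."""
    return FuzzyIndexes(
        mid=(e.short_lo + e.short_hi) / 2,
        spr=(e.short_hi - e.short_lo) / 2,
        sprl=e.short_lo - e.long_lo,
        sprr=e.long_hi - e.short_hi,
    )


def to_trapezoid(
    f: FuzzyIndexes, patient_id: str = "", rater_role: str = "unknown"
) -> TrapezoidEvaluation:
    """Inverse of :func:`parameterize`: rebuild the short and long ranges."""
    short_lo = f.mid - f.spr
    short_hi = f.mid + f.spr
    return TrapezoidEvaluation(
        patient_id=patient_id,
        short_lo=short_lo,
        short_hi=short_hi,
        long_lo=short_lo - f.sprl,
        long_hi=short_hi + f.sprr,
        rater_role=rater_role,
    )


def average_indexes(items: Sequence[FuzzyIndexes] | Iterable[FuzzyIndexes]) -> FuzzyIndexes:
    """Componentwise mean of index sets: one subjective risk per patient.

    Equivalent to the pointwise (Minkowski) mean of the underlying
    trapezoids; the constraint set is convex, so the mean is always valid.
    """
    items = list(items)
    if not items:
        raise ValidationError("patient has no evaluations to average")
    arr = np.array([f.as_tuple() for f in items], dtype=float)
    m = arr.mean(axis=0)
    return FuzzyIndexes(*m)


# ---------------------------------------------------------------------------
# frame-level (bulk) operations


def validate_evaluation_frame(
    df: pd.DataFrame, repair_nesting: bool = False, source: str = "<frame>"
) -> pd.DataFrame:
    """Validate (optionally repair) a long-format evaluation table.

    With ``repair_nesting=True`` a long range that fails to contain its
    short range is expanded to the convex hull of both ranges and a warning
    is logged; otherwise the first offending row raises ValidationError.
    """
    missing = [c for c in EVALUATION_COLUMNS if c not in df.columns and c != "rater_role"]
    if missing:
        raise ValidationError(f"{source}: missing columns {missing}")
    df = df.copy()
    if "rater_role" not in df.columns:
        df["rater_role"] = "unknown"
    for col in ("short_lo", "short_hi", "long_lo", "long_hi"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < -_TOL) | (vals > 100 + _TOL)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{source}: column {col!r}, row {row}: value {df[col].iloc[row]!r} "
                "is not a percentage in [0, 100]"
            )
        df[col] = vals.astype(float)
    inverted = df["short_lo"] > df["short_hi"] + _TOL
    if inverted.any():
        row = int(np.flatnonzero(inverted.to_numpy())[0])
        raise ValidationError(f"{source}: row {row}: short_lo exceeds short_hi")
    not_nested = (df["long_lo"] > df["short_lo"] + _TOL) | (
        df["short_hi"] > df["long_hi"] + _TOL
    )
    if not_nested.any():
        if repair_nesting:
            n_bad = int(not_nested.sum())
            df.loc[not_nested, "long_lo"] = np.minimum(
                df.loc[not_nested, "long_lo"], df.loc[not_nested, "short_lo"]
            )
            df.loc[not_nested, "long_hi"] = np.maximum(
                df.loc[not_nested, "long_hi"], df.loc[not_nested, "short_hi"]
            )
            logger.warning(
                "%s: expanded the long range to contain the short range in "
                "%d evaluation(s)",
                source,
                n_bad,
            )
        else:
            row = int(np.flatnonzero(not_nested.to_numpy())[0])
            raise ValidationError(
                f"{source}: row {row}: long range does not contain the short "
                "range (pass repair_nesting=True to expand it)"
            )
    if "timestamp" in df.columns:
        parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
        if parsed.isna().any() and df["timestamp"].notna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise ValidationError(
                f"{source}: row {row}: timestamp {df['timestamp'].iloc[row]!r} "
                "is not ISO 8601"
            )
        df["timestamp"] = parsed
    return df


def read_evaluations(path: str | Path, repair_nesting: bool = False) -> pd.DataFrame:
    """Read the long-format evaluations CSV (one row per evaluation)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_evaluation_frame(df, repair_nesting=repair_nesting, source=str(path))


def parameterize_frame(evals: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`parameterize` over an evaluation table."""
    out = pd.DataFrame(
        {
            "patient_id": evals["patient_id"],
            "MID": (evals["short_lo"] + evals["short_hi"]) / 2,
            "SPR": (evals["short_hi"] - evals["short_lo"]) / 2,
            "SPRL": evals["short_lo"] - evals["long_lo"],
            "SPRR": evals["long_hi"] - evals["short_hi"],
        }
    )
    return out


def average_by_patient(evals: pd.DataFrame) -> pd.DataFrame:
    """Average all of a patient's evaluations into one set of indexes.

    Accepts either an evaluation table (short/long ranges) or an already
    parameterized table with MID/SPR/SPRL/SPRR columns.
    """
    if "MID" not in evals.columns:
        evals = parameterize_frame(evals)
    grouped = (
        evals.groupby("patient_id", sort=False)[list(INDEX_COLUMNS)]
        .mean()
        .reset_index()
    )
    return grouped


def write_patient_indexes(indexes: pd.DataFrame, path: str | Path) -> None:
    indexes.to_csv(path, index=False, columns=["patient_id", *INDEX_COLUMNS])


def read_patient_indexes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("patient_id", *INDEX_COLUMNS) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df
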