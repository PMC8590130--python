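"""Loading, validation and recoding of long-format longitudinal data.

A :class:`CosinorDataset` holds one row per observation — subject id,
time of day in hours, a continuous response, and optional categorical
covariates — plus the unit-circle rhythm regressor columns ``x`` and
``z`` appended by :func:`cosinormixed.core.recode_time_array`.  Rows
missing the response or the time are dropped with a logged count
(available-case analysis; mixed models remain valid under missing at
random, so no imputation is attempted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SpecificationError, recode_time_array

logger = logging.getLogger(__name__)

#: internal rhythm-regressor column names (cos and sin components)
X_COL = "x"
Z_COL = "z"

_RESERVED = {X_COL, Z_COL}


class SchemaError(SpecificationError):
    """Input data does not match the declared column roles."""


@dataclass
class CosinorDataset:
    """Validated long-format dataset with rhythm regressors attached.

    Attributes
    ----------
    records
        One row per retained observation; columns ``subject_id``,
        ``time``, ``response``, one column per covariate, and the
        regressors ``x`` and ``z``.
    period
        Cycle length in hours (24 for circadian data).
    covariates
        Names of the categorical covariate columns.
    n_dropped
        Rows removed because response or time was missing.
    """

    records: pd.DataFrame
    period: float
    covariates: list[str] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.records)

    @property
    def n_subjects(self) -> int:
        return self.records["subject_id"].nunique()

    def validate(self) -> None:
        df = self.records
        required = ["subject_id", "time", "response", X_COL, Z_COL]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"dataset records missing columns: {missing}")
        if df["subject_id"].isna().any() or df["time"].isna().any():
            raise SchemaError("subject_id and time must be non-missing")
        radius = df[X_COL].to_numpy() ** 2 + df[Z_COL].to_numpy() ** 2
        if len(df) and np.max(np.abs(radius - 1.0)) > 1e-12:
            raise SchemaError("rhythm regressors violate x^2 + z^2 = 1")
        for cov in self.covariates:
            if cov not in df.columns:
                raise SchemaError(f"declared covariate {cov!r} not in records")


def from_dataframe(
    df: pd.DataFrame,
    *,
    subject_col: str,
    time_col: str,
    response_col: str,
    covariate_cols: list[str] | None = None,
    period: float = 24.0,
) -> CosinorDataset:
    """Build a validated :class:`CosinorDataset` from a raw dataframe.

    Rows with missing response or time are dropped (count logged and
    recorded on the dataset).  Times are used modulo the period; no
    date arithmetic is performed.
    """
    if period <= 0 or not np.isfinite(period):
        raise SpecificationError(f"period must be positive, got {period!r}")
    covariate_cols = list(covariate_cols or [])
    roles = {
        "subject": subject_col,
        "time": time_col,
        "response": response_col,
        **{f"covariate {c}": c for c in covariate_cols},
    }
    missing = {role: col for role, col in roles.items() if col not in df.columns}
    if missing:
        raise SchemaError(
            "columns not found in input data: "
            + ", ".join(f"{col!r} (role: {role})" for role, col in missing.items())
        )
    bad = _RESERVED.intersection(covariate_cols)
    if bad:
        raise SchemaError(f"covariate names {sorted(bad)} collide with regressor columns")

    out = pd.DataFrame(
        {
            "subject_id": df[subject_col].astype(str),
            "time": _numeric(df[time_col], time_col),
            "response": _numeric(df[response_col], response_col),
        }
    )
    for c in covariate_cols:
        vals = df[c]
        out[c] = vals.astype(str).where(vals.notna(), other=pd.NA)

    keep = out["time"].notna() & out["response"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing time or response", n_dropped)
    out = out.loc[keep].reset_index(drop=True)

    x, z = recode_time_array(out["time"].to_numpy(dtype=float), period)
    out[X_COL] = x
    out[Z_COL] = z

    ds = CosinorDataset(
        records=out, period=float(period), covariates=covariate_cols, n_dropped=n_dropped
    )
    ds.validate()
    return ds


def _numeric(s: pd.Series, name: str) -> pd.Series:
    converted = pd.to_numeric(s, errors="coerce")
    bad = converted.isna() & s.notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"column {name!r} has a non-numeric value {s.iloc[idx]!r} at row {idx}"
        )
    return converted


def load_dataset(
    path: str | Path,
    column_map: dict,
    period: float = 24.0,
) -> CosinorDataset:
    """Read a delimited text file (comma or tab, header required).

    ``column_map`` maps roles to column names; required roles are
    ``subject``, ``time`` and ``response``, and an optional
    ``covariates`` entry lists categorical covariate columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for role in ("subject", "time", "response"):
        if role not in column_map:
            raise SchemaError(f"column_map is missing the required role {role!r}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return from_dataframe(
        df,
        subject_col=column_map["subject"],
        time_col=column_map["time"],
        response_col=column_map["response"],
        covariate_cols=list(column_map.get("covariates", [])),
        period=period,
    )


def write_dataset(ds: CosinorDataset, path: str | Path) -> None:
    """Write the long-format records (without x/z) as delimited text."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = [c for c in ds.records.columns if c not in _RESERVED]
    ds.records[cols].to_csv(path, sep=sep, index=False)


def summarize_dataset(ds: CosinorDataset) -> pd.DataFrame:
    """Per-subject observation counts and time-of-day coverage.

    A subject whose observations all fall at a single time point cannot
    identify a rhythm; such subjects are flagged ``no within-day spread``
    and a warning is logged.
    """
    if ds.n_obs == 0:
        return pd.DataFrame(
            columns=["subject_id", "n_obs", "time_min", "time_max", "flag"]
        )
    g = ds.records.groupby("subject_id", sort=True)["time"]
    summary = pd.DataFrame(
        {
            "n_obs": g.size(),
            "time_min": g.min(),
            "time_max": g.max(),
            "n_distinct_times": g.nunique(),
        }
    ).reset_index()
    summary["flag"] = np.where(
        summary["n_distinct_times"] == 1, "no within-day spread", ""
    )
    n_flat = int((summary["flag"] != "").sum())
    if n_flat:
        logger.warning("%d subject(s) have no within-day time spread", n_flat)
    return summary
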