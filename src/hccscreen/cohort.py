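"""Cohort data model, delimited-text I/O and preprocessing.

A screening cohort is held as a pair of :class:`pandas.DataFrame` objects:

``patients``
    One row per patient: ``id`` (unique), ``delta`` (1 = HCC case, 0 =
    control), ``d`` (months from HCV index to HCC diagnosis for cases, or to
    end of study for controls; strictly positive), ``baseline_age`` (years),
    and optional ``sex`` / ``race`` columns.

``visits``
    One row per AFP screening visit: ``patient_id``, ``t`` (months since HCV
    index), ``afp`` (ng/ml, > 0).  Preprocessing adds ``alt`` / ``plt``
    (most recent concurrent lab within the prior six months), ``age`` (years
    at test), ``dafp_obs`` / ``dafp_rate`` (annualised rate of change of
    log2 AFP when the previous test is within a year) and ``lab_eligible``.

All times are real-valued months measured from the HCV index date.  AFP, ALT
and PLT are floored at 1 before any log2 transform.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "SchemaError",
    "load_cohort",
    "write_cohort",
    "collapse_same_day",
    "attach_concurrent_labs",
    "compute_delta_afp",
    "label_six_month_outcome",
    "preprocess",
]

#: Months before the AFP draw within which an ALT/PLT counts as concurrent.
LAB_WINDOW_MONTHS = 6.0
#: Maximum age (months) of the previous AFP for the rate of change to count.
DAFP_WINDOW_MONTHS = 12.0

PATIENT_COLUMNS = ("id", "delta", "d", "baseline_age")
VISIT_COLUMNS = ("patient_id", "t", "afp")
LAB_COLUMNS = ("patient_id", "analyte", "value", "t")


class SchemaError(ValueError):
    """A required column is missing or a field fails validation."""


@dataclasses.dataclass
class Cohort:
    """A validated screening cohort.

    Attributes
    ----------
    patients, visits, labs : pandas.DataFrame
        See module docstring for the column contracts.
    dropped : pandas.DataFrame
        Visit rows excluded during loading (non-positive AFP), with a
        ``reason`` column.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    labs: pd.DataFrame | None = None
    dropped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.patients["id"].duplicated().any():
            raise SchemaError("duplicate patient ids")
        if not set(self.patients["delta"].unique()) <= {0, 1}:
            raise SchemaError("delta must be 0 or 1")
        if (self.patients["d"] <= 0).any():
            raise SchemaError("endpoint d must be positive")
        unknown = set(self.visits["patient_id"]) - set(self.patients["id"])
        if unknown:
            raise SchemaError(f"visits reference unknown patients: {sorted(unknown)[:5]}")

    @property
    def n_cases(self) -> int:
        return int((self.patients["delta"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.patients["delta"] == 0).sum())

    def subset(self, patient_ids) -> "Cohort":
        """Restrict the cohort to the given patients (order preserved)."""
        ids = pd.Index(patient_ids)
        pat = self.patients.set_index("id").loc[ids].reset_index()
        vis = self.visits[self.visits["patient_id"].isin(ids)].reset_index(drop=True)
        labs = None
        if self.labs is not None:
            labs = self.labs[self.labs["patient_id"].isin(ids)].reset_index(drop=True)
        return Cohort(pat, vis, labs)


def _require(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} file missing required columns: {missing}")


def load_cohort(
    patients_path: str | Path,
    visits_path: str | Path,
    labs_path: str | Path | None = None,
) -> Cohort:
    """Read a cohort from the comma-delimited on-disk schema.

    Rows with non-positive AFP are excluded (the cohort inclusion rule
    requires a valid AFP > 0 ng/ml) and reported in ``Cohort.dropped``.
    Visits are sorted and same-day duplicates collapsed on the log2 scale.
    """
    patients = pd.read_csv(patients_path)
    visits = pd.read_csv(visits_path)
    _require(patients, PATIENT_COLUMNS, "patients")
    _require(visits, VISIT_COLUMNS, "visits")
    for df, col, name in ((patients, "d", "patients"), (visits, "t", "visits"), (visits, "afp", "visits")):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[:5].tolist()
            raise SchemaError(f"non-numeric {col!r} in {name} file at rows {bad}") from exc

    bad = visits["afp"] <= 0
    dropped = visits[bad].assign(reason="afp <= 0").reset_index(drop=True)
    visits = visits[~bad].reset_index(drop=True)
    visits = collapse_same_day(visits, "afp")

    labs = None
    if labs_path is not None:
        labs = pd.read_csv(labs_path)
        _require(labs, LAB_COLUMNS, "labs")
        labs["value"] = pd.to_numeric(labs["value"])
        labs["t"] = pd.to_numeric(labs["t"])
        if (labs["value"] < 0).any():
            raise SchemaError("negative laboratory value")
    return Cohort(patients, visits, labs, dropped)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort back to the CSV schema; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pat_cols = [c for c in ("id", "delta", "d", "baseline_age", "sex", "race") if c in cohort.patients.columns]
    paths["patients"] = outdir / "patients.csv"
    cohort.patients[pat_cols].to_csv(paths["patients"], index=False)
    paths["visits"] = outdir / "visits.csv"
    cohort.visits[list(VISIT_COLUMNS)].to_csv(paths["visits"], index=False)
    if cohort.labs is not None:
        paths["labs"] = outdir / "labs.csv"
        cohort.labs[list(LAB_COLUMNS)].to_csv(paths["labs"], index=False)
    return paths


def collapse_same_day(visits: pd.DataFrame, value_col: str, floor: float | None = None) -> pd.DataFrame:
    """Collapse same-day repeat measurements to the anti-log2 of the mean of
    their log2 values (a geometric mean), then sort visits within patient.

    ``floor``, when given, truncates values below it before the log2 (used
    for ALT/PLT, which the risk model floors at 1).  AFP is collapsed raw:
    positivity is validated at load and the PEB standardisation must see the
    untruncated level.  Idempotent.
    """
    v = visits.copy()
    vals = v[value_col] if floor is None else np.maximum(v[value_col], floor)
    v["_log2"] = np.log2(vals)
    grouped = (
        v.groupby(["patient_id", "t"], as_index=False, sort=False)
        .agg({"_log2": "mean"})
        .assign(**{value_col: lambda d: np.exp2(d["_log2"])})
        .drop(columns="_log2")
    )
    extra = [c for c in visits.columns if c not in grouped.columns]
    if extra:
        first = v.groupby(["patient_id", "t"], as_index=False, sort=False)[extra].first()
        grouped = grouped.merge(first, on=["patient_id", "t"])
    return grouped.sort_values(["patient_id", "t"], kind="mergesort").reset_index(drop=True)


def attach_concurrent_labs(visits: pd.DataFrame, labs: pd.DataFrame | None) -> pd.DataFrame:
    """Attach the most recent ALT and PLT within ``[t - 6, t]`` to each visit.

    Same-day repeat lab values are first collapsed on the log2 scale.  Visits
    without both a concurrent ALT and PLT get ``lab_eligible = False``; they
    remain usable by the AFP-only and PEB algorithms.
    """
    out = visits.copy()
    out["alt"] = np.nan
    out["plt"] = np.nan
    if labs is not None and len(labs):
        if (labs["value"] < 0).any():
            raise SchemaError("negative laboratory value")
        for analyte, col in (("ALT", "alt"), ("PLT", "plt")):
            sub = labs[labs["analyte"] == analyte][["patient_id", "t", "value"]]
            if not len(sub):
                continue
            sub = collapse_same_day(sub, "value", floor=1.0).sort_values(["patient_id", "t"], kind="mergesort")
            merged = pd.merge_asof(
                out[["patient_id", "t"]].reset_index().sort_values("t", kind="mergesort"),
                sub.rename(columns={"t": "lab_t"}).sort_values("lab_t", kind="mergesort"),
                left_on="t",
                right_on="lab_t",
                by="patient_id",
                direction="backward",
                tolerance=LAB_WINDOW_MONTHS,
            ).set_index("index")
            out[col] = merged["value"].reindex(out.index)
    out["lab_eligible"] = out["alt"].notna() & out["plt"].notna()
    return out


def compute_delta_afp(visits: pd.DataFrame) -> pd.DataFrame:
    """Annualised rate of change of log2(AFP) since the previous test.

    ``dafp_obs`` is 1 when the previous AFP test is within 12 months; the
    rate is ``[log2(AFP_j) - log2(AFP_{j-1})] / [(t_j - t_{j-1}) / 12]`` and
    is only defined when observed.  The first visit of every patient has
    ``dafp_obs = 0``.
    """
    v = visits.sort_values(["patient_id", "t"], kind="mergesort").copy()
    log2_afp = np.log2(np.maximum(v["afp"], 1.0))
    prev_t = v.groupby("patient_id")["t"].shift(1)
    prev_y = log2_afp.groupby(v["patient_id"]).shift(1)
    gap = v["t"] - prev_t
    if (gap <= 0).any():
        raise RuntimeError("non-increasing visit times after same-day collapsing")
    obs = (gap <= DAFP_WINDOW_MONTHS) & prev_t.notna()
    v["dafp_obs"] = obs.astype(int)
    v["dafp_rate"] = np.where(obs, (log2_afp - prev_y) / (gap / 12.0), np.nan)
    return v.reset_index(drop=True)


def label_six_month_outcome(visits: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    """Indicator of HCC diagnosis within six months of the visit.

    ``D = 1`` iff the patient is a case and ``d < t + 6`` (strict).
    """
    info = patients.set_index("id")[["delta", "d"]]
    delta = visits["patient_id"].map(info["delta"]).to_numpy()
    d = visits["patient_id"].map(info["d"]).to_numpy()
    return pd.Series(((delta == 1) & (d < visits["t"].to_numpy() + 6.0)).astype(int), index=visits.index, name="D")


def preprocess(cohort: Cohort) -> pd.DataFrame:
    """Full visit-level preprocessing: labs, age at test, AFP rate of change,
    six-month outcome and patient endpoint columns.

    Returns the augmented visits table; the input cohort is not modified.
    """
    visits = attach_concurrent_labs(cohort.visits, cohort.labs)
    visits = compute_delta_afp(visits)
    info = cohort.patients.set_index("id")
    visits["age"] = visits["patient_id"].map(info["baseline_age"]) + visits["t"] / 12.0
    visits["delta"] = visits["patient_id"].map(info["delta"])
    visits["d"] = visits["patient_id"].map(info["d"])
    visits["D"] = label_six_month_outcome(visits, cohort.patients)
    return visits
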