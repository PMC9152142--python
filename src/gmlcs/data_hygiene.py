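"""Preprocessing operators applied before any model is fitted.

The fixed pipeline order is: univariate 4-SD screen (on raw values, per
variable per occasion) -> multivariate Mahalanobis screen (across occasions
within a variable, complete cases) -> intracranial-volume adjustment of the
VBM indicators -> longitudinal ("stack then rescale") standardization.
Detection happens on raw values; standardization is an affine transform
shared across occasions of a variable, so the relative mean differences
between occasions survive it.

All SDs use the n-1 (sample) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .studytable import FITNESS_OCCASIONS, FITNESS_VARIABLE, StudyTable
from .synthetic_data import TrainingLog


@dataclass
class OutlierReport:
    """What a screening pass looked at and what it removed."""

    univariate_flags: list[tuple[str, str, int, float]] = field(default_factory=list)
    multivariate_flags: list[tuple[str, str, float, float]] = field(default_factory=list)
    cells_examined: int = 0
    cells_discarded: int = 0

    def __post_init__(self) -> None:
        if self.cells_discarded > self.cells_examined:
            raise ValueError("cells_discarded cannot exceed cells_examined")

    def to_frame(self) -> pd.DataFrame:
        uni = pd.DataFrame(
            self.univariate_flags,
            columns=["participant_id", "variable", "occasion", "z"],
        )
        uni["kind"] = "univariate"
        multi = pd.DataFrame(
            self.multivariate_flags,
            columns=["participant_id", "variable", "distance_sq", "threshold"],
        )
        multi["kind"] = "multivariate"
        return pd.concat([uni, multi], ignore_index=True)


@dataclass
class ComplianceRecord:
    participant: str
    total_minutes: float
    longest_pause_weeks: int
    wattage_trend: float
    compliant: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.compliant != (not self.reasons):
            raise ValueError("compliant flag must mirror an empty reasons list")


# ----------------------------------------------------------------------
def adjust_for_icv(values: pd.Series, icv: pd.Series) -> pd.Series:
    """ANCOVA-style adjustment of ROI volumes for intracranial volume.

    adjusted = raw - b * (ICV - mean ICV), with b the least-squares slope of
    the ROI values on ICV over participants where both are observed.  The
    adjusted values have (numerically) zero sample covariance with ICV.
    Missing values stay missing.
    """
    values = values.astype(float)
    icv = icv.astype(float).reindex(values.index)
    ok = values.notna() & icv.notna()
    if ok.sum() < 3:
        raise ValueError(f"need >=3 non-missing (value, ICV) pairs, have {int(ok.sum())}")
    x = icv[ok].to_numpy()
    y = values[ok].to_numpy()
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        raise ValueError("ICV has zero variance; adjustment slope undefined")
    b = float(xc @ (y - y.mean())) / denom
    icv_mean = x.mean()
    return values - b * (icv - icv_mean)


def adjust_table_for_icv(table: StudyTable, modality: str = "VBM") -> StudyTable:
    """Apply :func:`adjust_for_icv` to every (variable, occasion) cell group of
    the given modality, using the participants table's ICV column."""
    icv = table.participants.set_index("participant_id")["icv"]
    meas = table.measurements.copy()
    target = meas["variable"].str.endswith(f".{modality}")
    for (_, _), idx in meas[target].groupby(["variable", "occasion"]).groups.items():
        sub = meas.loc[idx]
        vals = pd.Series(sub["value"].to_numpy(), index=sub["participant_id"])
        adj = adjust_for_icv(vals, icv)
        meas.loc[idx, "value"] = adj.to_numpy()
    return table.with_values(meas)


def stack_standardize(table: StudyTable, variable: str) -> StudyTable:
    """Rescale one variable to pooled mean 0 / SD 1 across *all* occasions.

    A single location/scale is shared by every occasion, so mean differences
    between occasions are preserved up to the common scale.
    """
    meas = table.measurements.copy()
    mask = meas["variable"] == variable
    vals = meas.loc[mask, "value"]
    if vals.notna().sum() < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 observed values")
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise ValueError(f"variable {variable!r} has zero pooled SD; cannot rescale")
    meas.loc[mask, "value"] = (vals - float(vals.mean())) / sd
    return table.with_values(meas)


def stack_standardize_all(table: StudyTable, variables: list[str] | None = None) -> StudyTable:
    out = table
    for v in variables if variables is not None else out.variables():
        out = stack_standardize(out, v)
    return out


def flag_univariate_outliers(
    table: StudyTable, threshold_sd: float = 4.0
) -> tuple[StudyTable, OutlierReport]:
    """Flag cells further than ``threshold_sd`` sample SDs from their
    (variable, occasion) group mean; flagged cells are removed from the
    returned table.  Zero-spread groups flag nothing."""
    meas = table.measurements
    flags: list[tuple[str, str, int, float]] = []
    for (var, occ), sub in meas.groupby(["variable", "occasion"]):
        mu = float(sub["value"].mean())
        sd = float(sub["value"].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (sub["value"] - mu) / sd
        for pid, zz in zip(sub.loc[z.abs() > threshold_sd, "participant_id"], z[z.abs() > threshold_sd]):
            flags.append((pid, var, int(occ), float(zz)))
    report = OutlierReport(
        univariate_flags=flags,
        cells_examined=len(meas),
        cells_discarded=len(flags),
    )
    cleaned = table.drop_cells([(p, v, t) for p, v, t, _ in flags])
    return cleaned, report


def mahalanobis_threshold(n_occasions: int, criterion: float = 0.001) -> float:
    """Chi-square cutoff for the squared Mahalanobis distance at probability
    1 - criterion with df = number of occasions."""
    return float(stats.chi2.ppf(1.0 - criterion, df=n_occasions))


def flag_multivariate_outliers(
    table: StudyTable, variable: str, criterion: float = 0.001
) -> tuple[StudyTable, OutlierReport]:
    """Mahalanobis screen of a variable's occasion-vector, complete cases only.

    Uses the classical product-moment covariance of complete cases; a case
    whose squared distance exceeds the chi-square quantile at 1 - criterion
    (df = number of occasions) has *all* its occasions of that variable
    removed from the returned table.
    """
    occasions = (
        FITNESS_OCCASIONS
        if variable == FITNESS_VARIABLE
        else tuple(sorted(table.measurements.loc[table.measurements["variable"] == variable, "occasion"].unique()))
    )
    wide = table.wide([variable], occasions={variable: occasions})
    cols = [f"{variable}@{t}" for t in occasions]
    complete = wide.dropna(subset=cols)
    df = len(occasions)
    if len(complete) < df + 2:
        raise ValueError(
            f"need at least {df + 2} complete cases for {variable!r}, have {len(complete)}"
        )
    x = complete[cols].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular occasion covariance for {variable!r}") from exc
    if np.linalg.cond(cov) > 1e12:
        raise ValueError(f"singular occasion covariance for {variable!r}")
    centered = x - mu
    d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    thr = mahalanobis_threshold(df, criterion)
    flagged = complete.index[d2 > thr]
    flags = [
        (pid, variable, float(dd), thr)
        for pid, dd in zip(complete.index, d2)
        if dd > thr
    ]
    report = OutlierReport(
        multivariate_flags=flags,
        cells_examined=int(complete[cols].size),
        cells_discarded=len(flagged) * df,
    )
    cells = [(pid, variable, t) for pid in flagged for t in occasions]
    return table.drop_cells(cells), report


def screen_study(
    table: StudyTable,
    variables: list[str] | None = None,
    threshold_sd: float = 4.0,
    criterion: float = 0.001,
) -> tuple[StudyTable, OutlierReport]:
    """Univariate screen then multivariate screen over the given variables
    (default: all), with reports merged."""
    table, uni = flag_univariate_outliers(table, threshold_sd)
    merged = OutlierReport(
        univariate_flags=uni.univariate_flags,
        cells_examined=uni.cells_examined,
        cells_discarded=uni.cells_discarded,
    )
    for v in variables if variables is not None else table.variables():
        table, rep = flag_multivariate_outliers(table, v, criterion)
        merged.multivariate_flags += rep.multivariate_flags
        merged.cells_discarded += rep.cells_discarded
    return table, merged


# ----------------------------------------------------------------------
def classify_compliance(
    log: TrainingLog,
    weeks_required: int = 21,
    weekly_minutes: float = 90.0,
    max_pause_weeks: int = 2,
    require_nondecreasing_watts: bool = False,
) -> ComplianceRecord:
    """Apply the study compliance rules to one weekly training log.

    Non-compliant iff total minutes fall below ``weeks_required *
    weekly_minutes``, any zero-activity pause exceeds ``max_pause_weeks``
    consecutive weeks, or (when required, i.e. for exercisers) the
    least-squares wattage trend over active weeks is negative.
    """
    total = float(sum(log.minutes))
    # longest run of zero-minute weeks, counting gaps in week numbering as zero
    longest = run = 0
    prev_week = None
    for week, minutes in zip(log.weeks, log.minutes):
        if prev_week is not None and week > prev_week + 1:
            run += week - prev_week - 1
        if minutes == 0:
            run += 1
        else:
            longest = max(longest, run)
            run = 0
        prev_week = week
    longest = max(longest, run)

    active = [(w, p) for w, m, p in zip(log.weeks, log.minutes, log.watts) if m > 0]
    if len(active) >= 2:
        wk = np.array([w for w, _ in active], dtype=float)
        pw = np.array([p for _, p in active], dtype=float)
        slope = float(np.polyfit(wk, pw, 1)[0])
    else:
        slope = 0.0

    reasons = []
    if total < weeks_required * weekly_minutes:
        reasons.append("minutes")
    if longest > max_pause_weeks:
        reasons.append("pause")
    if require_nondecreasing_watts and slope < -1e-8:
        reasons.append("watts")
    return ComplianceRecord(
        participant=log.participant,
        total_minutes=total,
        longest_pause_weeks=int(longest),
        wattage_trend=slope,
        compliant=not reasons,
        reasons=reasons,
    )


def apply_compliance_exclusion(
    table: StudyTable, records: dict[str, ComplianceRecord], mode: str = "t1-retained"
) -> StudyTable:
    """Drop occasion-2/3 measurements of non-compliant participants.

    ``mode='t1-retained'`` keeps their baseline rows (the study's choice, on
    the assumption that non-compliers do not differ at baseline);
    ``mode='fully-excluded'`` removes them entirely.
    """
    if mode not in ("t1-retained", "fully-excluded"):
        raise ValueError(f"unknown exclusion mode {mode!r}")
    bad = {p for p, r in records.items() if not r.compliant}
    meas = table.measurements
    drop = meas["participant_id"].isin(bad)
    if mode == "t1-retained":
        drop &= meas["occasion"] > 1
    return table.with_values(meas.loc[~drop].copy())
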