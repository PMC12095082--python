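"""Selection, spline fitting, QC and BMI-grid construction for growth records.

Raw input is long-format anthropometry: one row per visit with child id, sex,
age, height (cm) and weight (kg).  Children are screened with three
selection rules — earliest non-birth measurement before 6 months, last
measurement at or after 16 years, and no gap of 5+ years between consecutive
measurements — applied to the height and the weight series separately.

Height and weight are then fitted per child with least-squares B-splines
(knots at the child's min and max observed ages plus fixed interior knots at
3, 12, 48, 96 and 144 months), or with piecewise-linear interpolation in
sensitivity mode.  Fitted curves whose value falls by more than 1 cm
(height) or 2 kg (weight) below their running maximum are flagged; a height
flag excludes the child, a weight flag excludes only when the raw
observations show no comparable decrease (an automated stand-in for a manual
review of spline anomalies).

BMI is finally computed as weight / (height/100)^2 on a standard grid of 34
shared ages: 3, 6, 9 and 12 months, then every 6 months up to 16 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_lsq_spline

__all__ = [
    "GrowthRecordSet",
    "SelectionReport",
    "FittedCurve",
    "BMIGrid",
    "standard_grid",
    "refine_grid",
    "apply_selection_criteria",
    "fit_growth_spline",
    "fit_growth_linear",
    "qc_decreasing",
    "build_bmi_grid",
    "preprocess_cohort",
    "DomainError",
    "TooFewPointsError",
]

#: two weeks — separates delivery records from first well-child check-ups
BIRTH_EPSILON = 14.0 / 365.25

#: fixed interior spline knots, in months
INTERIOR_KNOTS_MONTHS = (3.0, 12.0, 48.0, 96.0, 144.0)

#: how far (years) beyond a child's observed age range fitted curves may be
#: evaluated; the standard grid starts at 0.25 y while first visits may fall
#: slightly later, so a small amount of extrapolation is unavoidable
EXTRAPOLATION_LIMIT = 0.5

HEIGHT_DROP_CM = 1.0
WEIGHT_DROP_KG = 2.0

_EXCLUSION_REASONS = ("late_first", "short_followup", "long_gap",
                      "qc_anomaly", "too_few_points")


class DomainError(ValueError):
    """Requested evaluation outside the admissible age range."""


class TooFewPointsError(ValueError):
    """Not enough observations to fit the requested curve."""


def standard_grid() -> np.ndarray:
    """The 34 standard BMI ages (years): 0.25, 0.5, 0.75, 1.0, 1.5, ..., 16.0."""
    return np.concatenate([[0.25, 0.5, 0.75, 1.0], np.arange(1.5, 16.0 + 1e-9, 0.5)])


def refine_grid(grid, factor: int = 4) -> np.ndarray:
    """Uniformly refine a grid ``factor``-fold (for dense QC evaluation)."""
    grid = np.asarray(grid, dtype=float)
    out = [grid[:1]]
    for a, b in zip(grid[:-1], grid[1:]):
        out.append(np.linspace(a, b, factor + 1)[1:])
    return np.concatenate(out)


class GrowthRecordSet:
    """Long-format visit records, screened and deduplicated.

    Columns: ``child_id, sex, age_years, height_cm, weight_kg``.  Heights
    outside (30, 230) cm and weights outside (1, 250) kg are implausible and
    set to missing; duplicate (child, age) rows are averaged per measure so
    the result is independent of input row order.
    """

    REQUIRED = ("child_id", "sex", "age_years", "height_cm", "weight_kg")

    #: divisor converting the input age unit to years
    AGE_UNIT_DIVISORS = {"years": 1.0, "months": 12.0, "days": 365.25}

    def __init__(self, df: pd.DataFrame, age_unit: str = "years"):
        if age_unit not in self.AGE_UNIT_DIVISORS:
            raise ValueError(f"age_unit must be one of {sorted(self.AGE_UNIT_DIVISORS)}")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["age_years"] = pd.to_numeric(df["age_years"]) / self.AGE_UNIT_DIVISORS[age_unit]
        if (df["age_years"] < 0).any():
            raise ValueError("ages must be nonnegative")
        bad_sex = ~df["sex"].isin(["F", "M"])
        if bad_sex.any():
            raise ValueError("sex must be 'F' or 'M'")
        for col, lo, hi in (("height_cm", 30.0, 230.0), ("weight_kg", 1.0, 250.0)):
            v = pd.to_numeric(df[col])
            df[col] = v.where((v > lo) & (v < hi))
        df = (df.groupby(["child_id", "sex", "age_years"], as_index=False)
                [["height_cm", "weight_kg"]].mean()
                .sort_values(["child_id", "age_years"], kind="mergesort")
                .reset_index(drop=True))
        self.df = df

    @property
    def child_ids(self) -> list:
        return sorted(self.df["child_id"].unique())

    def sex_of(self, child_id) -> str:
        return self.df.loc[self.df["child_id"] == child_id, "sex"].iloc[0]

    def series(self, child_id, measure: str):
        """(ages, values) for one child and measure, missing values dropped."""
        col = {"height": "height_cm", "weight": "weight_kg"}[measure]
        sub = self.df[self.df["child_id"] == child_id]
        mask = sub[col].notna()
        return sub.loc[mask, "age_years"].to_numpy(), sub.loc[mask, col].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SelectionReport:
    """Partition of the input children into kept and excluded (with reason)."""

    kept_ids: list
    excluded: dict  # child_id -> reason

    def __post_init__(self):
        bad = set(self.excluded.values()) - set(_EXCLUSION_REASONS)
        if bad:
            raise ValueError(f"unknown exclusion reasons: {bad}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, "kept", "") for cid in self.kept_ids]
        rows += [(cid, "excluded", r) for cid, r in sorted(self.excluded.items())]
        return pd.DataFrame(rows, columns=["child_id", "status", "reason"])


@dataclass
class FittedCurve:
    child_id: object
    measure: str  # height | weight
    grid_ages: np.ndarray
    values: np.ndarray
    qc_flags: list = field(default_factory=list)  # (age, drop magnitude)

    def __post_init__(self):
        self.grid_ages = np.asarray(self.grid_ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid_ages.shape != self.values.shape:
            raise ValueError("grid_ages and values must match")
        if np.any(np.diff(self.grid_ages) <= 0):
            raise ValueError("grid_ages must be strictly increasing")


@dataclass
class BMIGrid:
    """n_children x 34 BMI matrix on the standard age grid."""

    child_ids: list
    grid_ages: np.ndarray
    values: np.ndarray
    sex: list

    def __post_init__(self):
        self.grid_ages = np.asarray(self.grid_ages, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.grid_ages.size != 34 or self.values.shape[1] != 34:
            raise ValueError("BMI grid must have exactly 34 age columns")
        if self.values.shape[0] != len(self.child_ids) or len(self.sex) != len(self.child_ids):
            raise ValueError("row count must match child_ids and sex")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BMI values must be finite")
        if np.any(self.values <= 5.0) or np.any(self.values >= 80.0):
            raise ValueError("BMI values outside the plausible range (5, 80)")

    def subset(self, mask) -> "BMIGrid":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return BMIGrid(child_ids=[self.child_ids[i] for i in idx],
                       grid_ages=self.grid_ages,
                       values=self.values[idx],
                       sex=[self.sex[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bmi_{a:g}" for a in self.grid_ages]
        out = pd.DataFrame(self.values, columns=cols)
        out.insert(0, "sex", self.sex)
        out.insert(0, "child_id", self.child_ids)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BMIGrid":
        bmi_cols = [c for c in df.columns if c.startswith("bmi_")]
        ages = np.array([float(c[4:]) for c in bmi_cols])
        return cls(child_ids=df["child_id"].tolist(), grid_ages=ages,
                   values=df[bmi_cols].to_numpy(dtype=float),
                   sex=df["sex"].tolist())


def _series_passes(ages: np.ndarray) -> str | None:
    """First failing selection rule for one measurement series, or None."""
    if ages.size == 0:
        return "too_few_points"
    if ages.min() >= 0.5:
        return "late_first"
    if ages.max() < 16.0:
        return "short_followup"
    if ages.size > 1 and np.any(np.diff(np.sort(ages)) >= 5.0):
        return "long_gap"
    return None


def apply_selection_criteria(records: GrowthRecordSet,
                             birth_epsilon: float = BIRTH_EPSILON,
                             series_rule: str = "both") -> SelectionReport:
    """Apply the measurement selection rules to every child.

    Birth measures (age <= ``birth_epsilon``) are excluded before testing.
    A series passes iff its earliest measurement is before 6 months, its last
    at or after 16 years, and no two consecutive measurements are 5+ years
    apart.  With ``series_rule='both'`` (default) a child is kept only if
    both the height and the weight series pass; ``'either'`` keeps the child
    if at least one does.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    if series_rule not in ("both", "either"):
        raise ValueError("series_rule must be 'both' or 'either'")
    kept, excluded = [], {}
    for cid in records.child_ids:
        reasons = []
        for measure in ("height", "weight"):
            ages, _ = records.series(cid, measure)
            ages = ages[ages > birth_epsilon]
            reasons.append(_series_passes(ages))
        fails = [r for r in reasons if r is not None]
        ok = (len(fails) == 0) if series_rule == "both" else (len(fails) < 2)
        if ok:
            kept.append(cid)
        else:
            excluded[cid] = fails[0]
    return SelectionReport(kept_ids=kept, excluded=excluded)


def _dedupe(ages: np.ndarray, values: np.ndarray):
    """Sort by age and average values at exactly duplicated ages."""
    order = np.argsort(ages, kind="mergesort")
    ages, values = ages[order], values[order]
    uniq, inv = np.unique(ages, return_inverse=True)
    if uniq.size != ages.size:
        sums = np.bincount(inv, weights=values)
        counts = np.bincount(inv)
        return uniq, sums / counts
    return ages, values


def _check_grid_domain(grid, lo, hi, extrapolation_limit):
    grid = np.asarray(grid, dtype=float)
    if grid.min() < lo - extrapolation_limit or grid.max() > hi + extrapolation_limit:
        raise DomainError(
            f"grid ages [{grid.min():g}, {grid.max():g}] extend more than "
            f"{extrapolation_limit:g} y beyond the observed range [{lo:g}, {hi:g}]")
    return grid


def fit_growth_spline(series, grid, child_id=None, measure: str = "height",
                      degree: int = 3,
                      interior_knots_months=INTERIOR_KNOTS_MONTHS,
                      extrapolation_limit: float = EXTRAPOLATION_LIMIT) -> FittedCurve:
    """Least-squares B-spline fit of one measurement series, on ``grid``.

    Knots sit at the child's min and max observed ages plus the fixed
    interior knots (given in months, converted to years); interior knots
    outside the observed range are dropped to keep the basis well posed.
    A rank-deficient fit is retried once with the degree reduced by one.
    """
    ages, values = _dedupe(*(np.asarray(a, dtype=float) for a in series))
    interior = np.asarray(interior_knots_months, dtype=float) / 12.0
    interior = interior[(interior > ages.min()) & (interior < ages.max())]
    if ages.size < degree + 1 + interior.size:
        raise TooFewPointsError(
            f"{ages.size} observations cannot support degree {degree} with "
            f"{interior.size} interior knots")
    grid = _check_grid_domain(grid, ages.min(), ages.max(), extrapolation_limit)

    def _fit(k: int) -> BSpline:
        knots = np.concatenate([[ages.min()] * (k + 1), interior, [ages.max()] * (k + 1)])
        return make_lsq_spline(ages, values, knots, k=k)

    try:
        spl = _fit(degree)
        if not np.all(np.isfinite(spl.c)):
            raise np.linalg.LinAlgError("non-finite spline coefficients")
    except (np.linalg.LinAlgError, ValueError):
        if degree <= 1:
            raise
        spl = _fit(degree - 1)
        if not np.all(np.isfinite(spl.c)):
            raise np.linalg.LinAlgError("spline fit failed at reduced degree")
    fitted = spl(grid)
    # guarded extrapolation: linear extension from the boundary value and
    # slope (raw polynomial extrapolation of a cubic is wildly unstable)
    lo_mask = grid < ages.min()
    hi_mask = grid > ages.max()
    if lo_mask.any():
        v0, d0 = spl(ages.min()), spl(ages.min(), nu=1)
        fitted[lo_mask] = v0 + d0 * (grid[lo_mask] - ages.min())
    if hi_mask.any():
        v1, d1 = spl(ages.max()), spl(ages.max(), nu=1)
        fitted[hi_mask] = v1 + d1 * (grid[hi_mask] - ages.max())
    return FittedCurve(child_id=child_id, measure=measure, grid_ages=grid, values=fitted)


def fit_growth_linear(series, grid, child_id=None, measure: str = "height",
                      extrapolation_limit: float = EXTRAPOLATION_LIMIT) -> FittedCurve:
    """Piecewise-linear interpolation of one series, evaluated on ``grid``.

    Sensitivity-mode counterpart of :func:`fit_growth_spline`.  Grid ages
    slightly outside the observed range (up to ``extrapolation_limit``) are
    linearly extrapolated from the end segments; farther ages raise
    :class:`DomainError`.
    """
    ages, values = _dedupe(*(np.asarray(a, dtype=float) for a in series))
    if ages.size < 2:
        raise TooFewPointsError("linear interpolation needs at least 2 observations")
    grid = _check_grid_domain(grid, ages.min(), ages.max(), extrapolation_limit)
    fitted = np.interp(grid, ages, values)
    # linear extrapolation at the ends (np.interp clamps)
    lo_mask = grid < ages[0]
    hi_mask = grid > ages[-1]
    if lo_mask.any():
        slope = (values[1] - values[0]) / (ages[1] - ages[0])
        fitted[lo_mask] = values[0] + slope * (grid[lo_mask] - ages[0])
    if hi_mask.any():
        slope = (values[-1] - values[-2]) / (ages[-1] - ages[-2])
        fitted[hi_mask] = values[-1] + slope * (grid[hi_mask] - ages[-1])
    return FittedCurve(child_id=child_id, measure=measure, grid_ages=grid, values=fitted)


def qc_decreasing(curve: FittedCurve, threshold: float) -> list:
    """Flag intervals where the fitted curve drops below its running maximum.

    Returns one ``(age, drop)`` flag per maximal contiguous interval on
    which the fitted value lies more than ``threshold`` below the running
    maximum, reporting the age and magnitude of the deepest drop.  Should be
    applied on a dense mesh (see :func:`refine_grid`).
    """
    v = curve.values
    drop = np.maximum.accumulate(v) - v
    mask = drop > threshold
    flags = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            k = i + int(np.argmax(drop[i:j + 1]))
            flags.append((float(curve.grid_ages[k]), float(drop[k])))
            i = j + 1
        else:
            i += 1
    return flags


def _raw_corroborates(raw_values: np.ndarray, threshold: float) -> bool:
    """Do the raw observations themselves fall >= threshold below their running max?"""
    if raw_values.size < 2:
        return False
    drop = np.maximum.accumulate(raw_values) - raw_values
    return bool(drop.max() >= threshold)


def build_bmi_grid(height: FittedCurve, weight: FittedCurve) -> np.ndarray:
    """BMI row (kg/m^2) from matched fitted height and weight curves."""
    if not np.array_equal(height.grid_ages, weight.grid_ages):
        raise ValueError("height and weight must be fitted on the same grid")
    if np.any(height.values <= 0):
        raise ValueError("fitted heights must be positive")
    return weight.values / (height.values / 100.0) ** 2


def preprocess_cohort(records: GrowthRecordSet, *, mode: str = "bspline",
                      degree: int = 3,
                      interior_knots_months=INTERIOR_KNOTS_MONTHS,
                      birth_epsilon: float = BIRTH_EPSILON,
                      series_rule: str = "both",
                      height_drop_cm: float = HEIGHT_DROP_CM,
                      weight_drop_kg: float = WEIGHT_DROP_KG,
                      extrapolation_limit: float = EXTRAPOLATION_LIMIT):
    """Run selection, curve fitting, QC and BMI-grid construction.

    Returns ``(bmi_grid, report, qc_frame)``: the BMI grid of surviving
    children, the final selection report (QC exclusions folded in), and a
    table of all QC flags raised.
    """
    if mode not in ("bspline", "linear"):
        raise ValueError("mode must be 'bspline' or 'linear'")
    report = apply_selection_criteria(records, birth_epsilon, series_rule)
    grid = standard_grid()
    dense = refine_grid(grid, 4)
    kept, excluded = [], dict(report.excluded)
    rows, sexes, qc_rows = [], [], []
    for cid in report.kept_ids:
        curves = {}
        reason = None
        for measure, thr in (("height", height_drop_cm), ("weight", weight_drop_kg)):
            ages, values = records.series(cid, measure)
            keep = ages > birth_epsilon
            ages, values = ages[keep], values[keep]
            try:
                if mode == "bspline":
                    fit = lambda g: fit_growth_spline((ages, values), g, cid, measure,
                                                      degree, interior_knots_months,
                                                      extrapolation_limit)
                else:
                    fit = lambda g: fit_growth_linear((ages, values), g, cid, measure,
                                                      extrapolation_limit)
                dense_curve = fit(dense)
                curve = fit(grid)
            except TooFewPointsError:
                reason = "too_few_points"
                break
            flags = qc_decreasing(dense_curve, thr)
            curve.qc_flags = flags
            for age, drop in flags:
                qc_rows.append((cid, measure, age, drop))
            if flags and (measure == "height" or not _raw_corroborates(values, thr)):
                reason = "qc_anomaly"
                break
            curves[measure] = curve
        if reason is not None:
            excluded[cid] = reason
            continue
        rows.append(build_bmi_grid(curves["height"], curves["weight"]))
        sexes.append(records.sex_of(cid))
        kept.append(cid)
    if not kept:
        raise ValueError("no children survived selection and QC")
    bmi = BMIGrid(child_ids=kept, grid_ages=grid, values=np.vstack(rows), sex=sexes)
    final = SelectionReport(kept_ids=kept, excluded=excluded)
    qc_frame = pd.DataFrame(qc_rows, columns=["child_id", "measure", "age", "drop"])
    return bmi, final, qc_frame
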