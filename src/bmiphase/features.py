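"""Timing features of BMI trajectories and cluster-level summaries.

Landmarks are detected discretely on the standard 34-point grid: after
collapsing runs of exactly equal values to their first grid index, an
interior point is a peak (valley) if both collapsed neighbors are strictly
lower (higher); grid endpoints are never landmarks.  From the landmarks we
derive the features reported per cluster in this analysis:

* age at first peak (the infancy peak),
* age at first valley after that peak (the adiposity rebound point),
* infancy slope — average BMI change from the start of the trajectory
  (3 months) to the first peak,
* childhood slope — average BMI change from the first peak to the first
  valley (nonpositive by construction),
* duration of the childhood BMI decrease (valley age minus peak age),
* total number of peaks.

Features that are undefined for a trajectory (no peak; peak at the first
grid point, which voids the infancy slope; no valley after the peak)
propagate as missing, which is why per-cluster summary counts differ
between feature columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .elastic import align_to_reference, curve_from_grid
from .preprocess import BMIGrid

__all__ = [
    "find_peaks_valleys",
    "trajectory_features",
    "features_table",
    "summarize_features_by_cluster",
    "peak_count_table",
    "aligned_cross_sections",
]

FEATURE_COLUMNS = ("age_first_peak", "age_first_valley", "infancy_slope",
                   "childhood_slope", "duration_decrease", "n_peaks")


def find_peaks_valleys(values, ages=None):
    """Discrete peaks and valleys of a gridded trajectory.

    Runs of exactly equal values collapse to their first index; interior
    collapsed points are peaks iff both neighbors are strictly lower and
    valleys iff strictly higher.  Endpoints are excluded.  Returns
    ``(peak_indices, valley_indices)`` into the original grid.
    """
    v = np.asarray(values, dtype=float)
    keep = np.concatenate([[0], np.flatnonzero(np.diff(v)) + 1])  # run starts
    cv = v[keep]
    peaks, valleys = [], []
    for i in range(1, cv.size - 1):
        if cv[i] > cv[i - 1] and cv[i] > cv[i + 1]:
            peaks.append(int(keep[i]))
        elif cv[i] < cv[i - 1] and cv[i] < cv[i + 1]:
            valleys.append(int(keep[i]))
    return peaks, valleys


def trajectory_features(values, ages) -> dict:
    """Timing features of one trajectory; undefined features are NaN."""
    v = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    peaks, valleys = find_peaks_valleys(v)
    out = dict.fromkeys(FEATURE_COLUMNS, np.nan)
    out["n_peaks"] = len(peaks)
    if not peaks:
        return out
    p = peaks[0]
    out["age_first_peak"] = ages[p]
    if p > 0:  # infancy slope undefined when the peak sits at the first grid age
        out["infancy_slope"] = (v[p] - v[0]) / (ages[p] - ages[0])
    later_valleys = [k for k in valleys if k > p]
    if later_valleys:
        q = later_valleys[0]
        out["age_first_valley"] = ages[q]
        out["duration_decrease"] = ages[q] - ages[p]
        out["childhood_slope"] = (v[q] - v[p]) / (ages[q] - ages[p])
    return out


def features_table(grid: BMIGrid) -> pd.DataFrame:
    """Per-child feature table for a whole BMI grid."""
    rows = [trajectory_features(row, grid.grid_ages) for row in grid.values]
    out = pd.DataFrame(rows)
    out.insert(0, "child_id", grid.child_ids)
    return out


def summarize_features_by_cluster(features: pd.DataFrame,
                                  assignment: ClusterAssignment,
                                  sex: str | None = None) -> pd.DataFrame:
    """Median, quartiles and n of each feature per cluster.

    Quantiles use the linear-interpolation convention.  ``n`` counts defined
    values only, so it varies between features within a cluster.
    """
    lab = pd.Series(assignment.labels, index=assignment.ids, name="cluster")
    df = features.set_index("child_id").join(lab, how="inner")
    if df["cluster"].isna().any():
        raise ValueError("features must cover all clustered children")
    rows = []
    for c, sub in df.groupby("cluster"):
        if len(sub) == 0:
            raise ValueError(f"cluster {c} is empty")
        for feat in FEATURE_COLUMNS:
            vals = sub[feat].dropna().to_numpy(dtype=float)
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append({"sex": sex, "cluster": int(c), "feature": feat,
                         "median": med, "q1": q1, "q3": q3, "n": vals.size})
    return pd.DataFrame(rows)


def peak_count_table(features: pd.DataFrame, assignment: ClusterAssignment,
                     cap: int = 3) -> pd.DataFrame:
    """Counts and within-cluster percents of peak numbers (capped at ``cap``)."""
    lab = pd.Series(assignment.labels, index=assignment.ids, name="cluster")
    df = features.set_index("child_id").join(lab, how="inner")
    df["n_peaks_capped"] = df["n_peaks"].astype(int).clip(upper=cap)
    rows = []
    for c, sub in df.groupby("cluster"):
        total = len(sub)
        for cat in range(cap + 1):
            cnt = int((sub["n_peaks_capped"] == cat).sum())
            rows.append({"cluster": int(c), "n_peaks": cat, "count": cnt,
                         "percent": round(100.0 * cnt / total, 1)})
    return pd.DataFrame(rows)


def aligned_cross_sections(grid: BMIGrid, assignment: ClusterAssignment,
                           n_points: int = 101,
                           neighborhood_width: int = 7) -> pd.DataFrame:
    """Cluster mean BMI curves after alignment to the cluster medoid.

    Each member trajectory is elastically aligned to its cluster medoid,
    removing within-cluster phase variation; the cross-sectional mean and a
    normal-approximation 95% CI (mean +/- 1.96 sd/sqrt(n)) are then computed
    at every grid age.  Clusters of size one return the curve with an
    undefined CI.
    """
    id_index = {cid: i for i, cid in enumerate(grid.child_ids)}
    ages = grid.grid_ages
    s = (ages - ages[0]) / (ages[-1] - ages[0])  # grid ages on [0,1]
    rows = []
    for c in range(1, assignment.k + 1):
        members = [assignment.ids[i] for i in range(len(assignment.ids))
                   if assignment.labels[i] == c]
        ref = curve_from_grid(ages, grid.values[id_index[assignment.medoid_ids[c - 1]]],
                              n_points)
        curves = [curve_from_grid(ages, grid.values[id_index[cid]], n_points)
                  for cid in members]
        aligned, _ = align_to_reference(curves, ref, neighborhood_width)
        mat = np.vstack([np.interp(s, a.t, a.f) for a in aligned])
        mean = mat.mean(axis=0)
        n = mat.shape[0]
        if n > 1:
            half = 1.96 * mat.std(axis=0, ddof=1) / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.full_like(mean, np.nan)
        for j, age in enumerate(ages):
            rows.append({"cluster": c, "age": float(age), "mean_bmi": mean[j],
                         "ci_low": lo[j], "ci_high": hi[j], "n": n})
    return pd.DataFrame(rows)
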