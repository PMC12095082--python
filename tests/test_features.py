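"""Trajectory timing features, cluster summaries, aligned cross-sections."""

import numpy as np
import pandas as pd
import pytest

import bmiphase as bp
from bmiphase.features import features_table, FEATURE_COLUMNS


def make_assignment(ids, labels, medoid_ids):
    labels = np.asarray(labels)
    return bp.ClusterAssignment(ids=list(ids), labels=labels,
                                medoid_ids=list(medoid_ids),
                                k=len(medoid_ids), total_cost=0.0,
                                avg_silhouette=0.0,
                                silhouette_per_point=np.zeros(len(labels)))


class TestFindPeaksValleys:
    def test_monotone_has_no_landmarks(self, grid):
        peaks, valleys = bp.find_peaks_valleys(np.linspace(10, 20, 34))
        assert peaks == [] and valleys == []

    def test_peak_then_valley(self):
        v = np.concatenate([[10, 12], [14], np.linspace(13, 8, 8),
                            np.linspace(9, 15, 23)])
        peaks, valleys = bp.find_peaks_valleys(v)
        assert peaks == [2] and valleys == [10]

    def test_plateau_collapses_to_first_index(self):
        v = np.concatenate([np.linspace(10, 13, 10), [14, 15, 15, 14],
                            np.linspace(15, 21, 20)])
        peaks, valleys = bp.find_peaks_valleys(v)
        assert 11 in peaks  # first index of the 15,15 plateau
        assert len([p for p in peaks if 10 <= p <= 13]) == 1

    def test_endpoints_never_landmarks(self):
        v = np.concatenate([[20], np.linspace(15, 10, 16), np.linspace(11, 25, 17)])
        peaks, valleys = bp.find_peaks_valleys(v)
        assert 0 not in peaks and 33 not in peaks
        assert 0 not in valleys and 33 not in valleys


class TestTrajectoryFeatures:
    def test_infancy_slope_arithmetic(self, grid):
        # BMI 14.0 at 0.25 y rising to a peak of 17.0 at 0.75 y
        v = np.concatenate([[14.0, 16.0, 17.0], np.linspace(16.0, 12.0, 10),
                            np.linspace(12.2, 20.0, 21)])
        f = bp.trajectory_features(v, grid)
        assert f["age_first_peak"] == 0.75
        assert f["infancy_slope"] == pytest.approx(3.0 / 0.5)

    def test_childhood_slope_and_duration(self, grid):
        # peak 17.0 at 0.75 y (index 2), valley 15.0 at 5.0 y (index 11)
        v = np.concatenate([[14.0, 16.0, 17.0], np.linspace(16.8, 15.2, 8),
                            [15.0], np.linspace(15.3, 21.0, 22)])
        f = bp.trajectory_features(v, grid)
        assert f["age_first_valley"] == 5.0
        assert f["duration_decrease"] == pytest.approx(4.25)
        assert f["childhood_slope"] == pytest.approx(-2.0 / 4.25)

    def test_monotone_trajectory_all_undefined(self, grid):
        f = bp.trajectory_features(np.linspace(12, 22, 34), grid)
        assert f["n_peaks"] == 0
        for key in FEATURE_COLUMNS:
            if key != "n_peaks":
                assert np.isnan(f[key])

    def test_type1_template_landmarks(self, grid):
        v = bp.make_template_bmi(bp.default_cluster_params()[0], grid)
        f = bp.trajectory_features(v, grid)
        assert f["age_first_peak"] == 0.75
        assert f["n_peaks"] == 1
        assert f["childhood_slope"] < 0

    def test_duration_identity_cohort_wide(self, default_cohort):
        bmi, _, _ = bp.preprocess_cohort(default_cohort.records)
        feats = features_table(bmi)
        both = feats.dropna(subset=["age_first_peak", "age_first_valley"])
        assert len(both) > 0
        np.testing.assert_allclose(
            both["duration_decrease"],
            both["age_first_valley"] - both["age_first_peak"])
        assert (both["age_first_valley"] > both["age_first_peak"]).all()


class TestSummaries:
    def test_quartiles_linear_interpolation(self):
        feats = pd.DataFrame({"child_id": ["a", "b", "c"],
                              "age_first_peak": [0.75] * 3,
                              "age_first_valley": [5.0] * 3,
                              "infancy_slope": [2.0, 4.0, 6.0],
                              "childhood_slope": [-0.5] * 3,
                              "duration_decrease": [4.25] * 3,
                              "n_peaks": [1, 1, 1]})
        a = make_assignment(["a", "b", "c"], [1, 1, 1], ["a"])
        summary = bp.summarize_features_by_cluster(feats, a, "F")
        row = summary[(summary.cluster == 1) & (summary.feature == "infancy_slope")].iloc[0]
        assert (row["median"], row.q1, row.q3, row.n) == (4.0, 3.0, 5.0, 3)

    def test_all_undefined_feature(self):
        feats = pd.DataFrame({"child_id": ["a", "b"],
                              "age_first_peak": [np.nan, np.nan],
                              "age_first_valley": [np.nan, np.nan],
                              "infancy_slope": [np.nan, np.nan],
                              "childhood_slope": [np.nan, np.nan],
                              "duration_decrease": [np.nan, np.nan],
                              "n_peaks": [0, 0]})
        a = make_assignment(["a", "b"], [1, 2], ["a", "b"])
        summary = bp.summarize_features_by_cluster(feats, a)
        row = summary[(summary.cluster == 1) & (summary.feature == "infancy_slope")].iloc[0]
        assert row.n == 0 and np.isnan(row["median"])

    def test_singleton_cluster(self):
        feats = pd.DataFrame({"child_id": ["a", "b", "c"],
                              "age_first_peak": [0.75, 1.0, 1.0],
                              "age_first_valley": [4.0, 5.0, 5.0],
                              "infancy_slope": [3.0, 2.0, 2.5],
                              "childhood_slope": [-0.5, -0.4, -0.3],
                              "duration_decrease": [3.25, 4.0, 4.0],
                              "n_peaks": [1, 1, 1]})
        a = make_assignment(["a", "b", "c"], [2, 1, 1], ["b", "a"])
        summary = bp.summarize_features_by_cluster(feats, a)
        row = summary[(summary.cluster == 2) & (summary.feature == "infancy_slope")].iloc[0]
        assert row["median"] == row.q1 == row.q3 == 3.0 and row.n == 1


class TestPeakCounts:
    def test_single_category(self):
        feats = pd.DataFrame({"child_id": [f"c{i}" for i in range(10)],
                              "n_peaks": [1] * 10})
        a = make_assignment(feats.child_id, [1] * 10, ["c0"])
        tab = bp.peak_count_table(feats, a)
        one = tab[(tab.cluster == 1) & (tab.n_peaks == 1)].iloc[0]
        assert one["count"] == 10 and one.percent == 100.0

    def test_cap_rule_and_percent_sum(self):
        feats = pd.DataFrame({"child_id": list("abcde"),
                              "n_peaks": [0, 1, 2, 3, 4]})
        a = make_assignment(list("abcde"), [1] * 5, ["a"])
        tab = bp.peak_count_table(feats, a, cap=3)
        counts = tab.set_index("n_peaks")["count"]
        assert counts[3] == 2  # 3 and 4 both capped to 3
        assert tab.percent.sum() == pytest.approx(100.0, abs=0.2)

    def test_invariant_to_child_order(self):
        rng = np.random.default_rng(0)
        ids = [f"c{i}" for i in range(12)]
        feats = pd.DataFrame({"child_id": ids,
                              "n_peaks": rng.integers(0, 5, 12)})
        labels = rng.integers(1, 3, 12)
        labels[:2] = [1, 2]
        a = make_assignment(ids, labels, ["c0", "c1"])
        t1 = bp.peak_count_table(feats, a)
        perm = rng.permutation(12)
        t2 = bp.peak_count_table(feats.iloc[perm].reset_index(drop=True), a)
        pd.testing.assert_frame_equal(t1, t2)


class TestAlignedCrossSections:
    def test_identical_curves_zero_ci_width(self, grid):
        row = bp.make_template_bmi(bp.default_cluster_params()[0], grid)
        other = bp.make_template_bmi(bp.default_cluster_params()[2], grid)
        bmi = bp.BMIGrid(child_ids=["a", "b", "c", "d"], grid_ages=grid,
                         values=np.vstack([row, row, row, other]),
                         sex=["F"] * 4)
        a = make_assignment(["a", "b", "c", "d"], [1, 1, 1, 2], ["a", "d"])
        cs = bp.aligned_cross_sections(bmi, a)
        c1 = cs[cs.cluster == 1]
        np.testing.assert_allclose(c1.ci_high - c1.ci_low, 0.0, atol=1e-9)
        # mean equals the shared curve exactly, up to the deterministic
        # 34 -> 101 -> 34 linear resampling round trip
        t101 = np.linspace(0, 1, 101)
        s34 = (grid - grid[0]) / (grid[-1] - grid[0])
        roundtrip = np.interp(s34, t101, np.interp(t101, s34, row))
        np.testing.assert_allclose(c1.mean_bmi, roundtrip, atol=1e-9)
        # singleton cluster: mean returned, CI undefined
        c2 = cs[cs.cluster == 2]
        assert c2.ci_low.isna().all() and not c2.mean_bmi.isna().any()

    def test_mean_within_pointwise_envelope(self, template_grid):
        bmi, labels = template_grid
        D = bp.pairwise_distance_matrix(bmi)
        a = bp.pam(D, 3)
        cs = bp.aligned_cross_sections(bmi, a)
        env_lo = bmi.values.min() - 1e-9
        env_hi = bmi.values.max() + 1e-9
        assert cs.mean_bmi.between(env_lo, env_hi).all()

    def test_alignment_removes_relative_warps(self, template_grid):
        # members are warped copies of their cluster template; aligning to
        # the medoid must reproduce the medoid trajectory closely
        bmi, labels = template_grid
        D = bp.pairwise_distance_matrix(bmi)
        a = bp.pam(D, 3)
        cs = bp.aligned_cross_sections(bmi, a)
        idx = {cid: i for i, cid in enumerate(bmi.child_ids)}
        for c in range(1, 4):
            med_row = bmi.values[idx[a.medoid_ids[c - 1]]]
            sub = cs[cs.cluster == c]
            assert np.max(np.abs(sub.mean_bmi.to_numpy() - med_row)) <= 0.2

    def test_no_warps_reproduces_template(self, grid):
        # with phase noise absent alignment is trivial and the cluster mean
        # equals the template itself
        templates = bp.default_cluster_params()
        rows, ids, labels = [], [], []
        for ci, p in enumerate(templates, start=1):
            for j in range(4):
                rows.append(bp.make_template_bmi(p, grid))
                ids.append(f"T{ci}_{j}")
                labels.append(ci)
        bmi = bp.BMIGrid(child_ids=ids, grid_ages=grid,
                         values=np.vstack(rows), sex=["F"] * len(ids))
        a = make_assignment(ids, labels, ["T1_0", "T2_0", "T3_0"])
        cs = bp.aligned_cross_sections(bmi, a)
        for ci, p in enumerate(templates, start=1):
            tv = bp.make_template_bmi(p, grid)
            sub = cs[cs.cluster == ci]
            assert np.max(np.abs(sub.mean_bmi.to_numpy() - tv)) <= 0.2
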