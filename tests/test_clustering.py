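"""Lesion typing: k-means convention, prediction strength, screening, burden."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mslesions import clustering
from mslesions.clustering import (
    _min_pair_agreement,
    kmeans2,
    labeling_agreement,
    patient_burden,
    prediction_strength,
    ps_null_pvalue,
    screen_metrics,
    select_feature_sets,
)


def two_blobs(n=60, sep=8.0, seed=0, p=2):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n // 2, p))
    b = rng.standard_normal((n - n // 2, p)) + sep
    return np.vstack([a, b])


class TestKmeans2:
    def test_point_masses_perfect_split(self):
        X = np.array([[0.0, 0], [0, 0], [0, 0], [5, 5], [5, 5], [5, 5]])
        X = X + np.arange(6)[:, None] * 1e-9  # break exact zero SD
        model = kmeans2(X, seed=0)
        labels = clustering.assign_types(X, model)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_b_type_sign_convention(self, typing_features):
        X, is_b = typing_features
        model = kmeans2(X, seed=1)
        raw = model.centroids_raw()
        names = model.feature_names
        b_idx = [k for k, v in model.label_map.items() if v == "B"][0]
        a_idx = 1 - b_idx
        for m in ("FA", "uFA", "f_in"):
            j = names.index(m)
            assert raw[b_idx, j] < raw[a_idx, j]
        j = names.index("RD")
        assert raw[b_idx, j] > raw[a_idx, j]

    def test_seeded_determinism(self, typing_features):
        X, _ = typing_features
        m1, m2 = kmeans2(X, seed=5), kmeans2(X, seed=5)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert m1.label_map == m2.label_map

    def test_constant_feature_named_in_error(self):
        X = pd.DataFrame({"FA": [0.3, 0.4, 0.2, 0.5], "uAD": [3.0, 3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="uAD"):
            kmeans2(X, seed=0)

    def test_matches_sklearn_partition(self, typing_features):
        # independent cross-check of the internal Lloyd engine
        from sklearn.cluster import KMeans

        X, _ = typing_features
        Z = (X - X.mean()) / X.std(ddof=0)
        model = kmeans2(X, seed=2)
        ours = clustering.assign_types(X, model)
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(Z.to_numpy())
        agree = labeling_agreement(ours == "B", sk.labels_.astype(bool))
        assert agree > 0.999


class TestAssignTypes:
    def test_training_rows_get_model_labels(self, typing_features):
        X, _ = typing_features
        model = kmeans2(X, seed=3)
        l1 = clustering.assign_types(X, model)
        l2 = clustering.assign_types(X.copy(), model)
        assert np.array_equal(l1, l2)

    def test_centroid_point_gets_own_label(self, typing_features):
        X, _ = typing_features
        model = kmeans2(X, seed=4)
        raw = model.centroids_raw()
        for idx in (0, 1):
            lab = clustering.assign_types(raw[[idx]], model)
            assert lab[0] == model.label_map[idx]

    def test_equidistant_tie_goes_to_lower_index(self):
        from mslesions._kmeans import assign_nearest

        centers = np.array([[0.0], [2.0]])
        assert assign_nearest(np.array([[1.0]]), centers)[0] == 0
        # and assign_types reports the lower-index centroid's label
        model = clustering.ClusterModel(
            ["x0"], np.zeros(1), np.ones(1), centers, {0: "A", 1: "B"}
        )
        assert clustering.assign_types(np.array([[1.0]]), model)[0] == "A"

    def test_missing_feature_column_raises(self, typing_features):
        X, _ = typing_features
        model = kmeans2(X, seed=0)
        with pytest.raises(ValueError, match="missing feature"):
            clustering.assign_types(X.drop(columns=["FA"]), model)


def brute_force_min_pair_agreement(own, other):
    """Independent oracle: explicit loop over ordered within-cluster pairs."""
    ps = 1.0
    for j in set(own):
        members = [i for i in range(len(own)) if own[i] == j]
        if len(members) < 2:
            continue
        total = agree = 0
        for a in members:
            for b in members:
                if a == b:
                    continue
                total += 1
                agree += other[a] == other[b]
        ps = min(ps, agree / total)
    return ps


class TestPairAgreementOracle:
    @given(
        own=st.lists(st.integers(0, 1), min_size=2, max_size=12),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force(self, own):
        rng = np.random.default_rng(len(own))
        other = rng.integers(0, 2, len(own))
        got = _min_pair_agreement(np.array(own), np.array(other))
        assert got == pytest.approx(brute_force_min_pair_agreement(own, list(other)))

    def test_singleton_clusters_contribute_one(self):
        assert _min_pair_agreement(np.array([0, 1]), np.array([1, 0])) == 1.0


class TestPredictionStrength:
    def test_separated_clusters_give_one(self):
        X = two_blobs(40, sep=20.0)
        res = prediction_strength(X, n_splits=20, seed=0)
        assert res.mean_ps == pytest.approx(1.0)

    def test_splits_in_unit_interval(self):
        X = np.random.default_rng(0).standard_normal((30, 3))
        res = prediction_strength(X, n_splits=30, seed=1)
        assert np.all((res.splits >= 0) & (res.splits <= 1))
        assert res.mean_ps == pytest.approx(res.splits.mean())

    def test_synthetic_cohort_replicates_above_threshold(self, typing_features):
        X, _ = typing_features
        res = prediction_strength(X.iloc[:400], n_splits=50, seed=2)
        assert res.mean_ps > 0.8

    def test_duplicated_data_changes_little(self):
        X = two_blobs(60, sep=6.0, seed=3)
        r1 = prediction_strength(X, n_splits=50, seed=4)
        r2 = prediction_strength(np.vstack([X, X]), n_splits=50, seed=4)
        assert abs(r1.mean_ps - r2.mean_ps) < 0.05

    def test_row_shuffle_invariance_up_to_rng(self):
        X = two_blobs(80, sep=6.0, seed=5)
        perm = np.random.default_rng(6).permutation(80)
        r1 = prediction_strength(X, n_splits=100, seed=7)
        r2 = prediction_strength(X[perm], n_splits=100, seed=7)
        assert abs(r1.mean_ps - r2.mean_ps) < 0.03

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError, match="at least 8"):
            prediction_strength(np.zeros((6, 2)) + np.arange(6)[:, None], n_splits=2)

    def test_strata_reported(self, typing_features):
        X, is_b = typing_features
        strata = np.where(np.arange(len(X)) % 2 == 0, "even", "odd")
        res = prediction_strength(X.iloc[:300], n_splits=20, seed=8, strata=strata[:300])
        assert set(res.strata) == {"even", "odd"}
        for r in res.strata.values():
            assert 0.0 <= r.mean_ps <= 1.0


class TestNullPvalue:
    def test_minimum_attainable_p_for_clustered_data(self):
        X = two_blobs(60, sep=15.0, seed=9)
        res = ps_null_pvalue(X, n_perms=99, n_splits_null=10, seed=10, n_restarts=4)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_p_bounds(self):
        X = np.random.default_rng(11).standard_normal((24, 2))
        res = ps_null_pvalue(X, n_perms=9, n_splits_null=5, seed=12, n_restarts=3)
        assert 1.0 / 10.0 <= res.p_value <= 1.0

    def test_null_calibration_uniform(self):
        # on data with no multivariate structure the p-value follows the
        # discrete uniform add-one grid; check by a KS-style bound over
        # repeated independent datasets
        reps, n_perms = 200, 19
        rng = np.random.default_rng(13)
        pvals = np.empty(reps)
        for r in range(reps):
            X = rng.standard_normal((32, 2))
            pvals[r] = ps_null_pvalue(
                X, n_perms=n_perms, n_splits_null=5, seed=1000 + r, n_restarts=2
            ).p_value
        grid = np.arange(1, n_perms + 2) / (n_perms + 1)
        ecdf = np.array([(pvals <= g + 1e-12).mean() for g in grid])
        # KS 1% critical value for 200 samples ~ 1.63/sqrt(200) = 0.115
        assert np.max(np.abs(ecdf - grid)) < 0.125


class TestScreening:
    def test_ceiling_fraction_discards(self):
        rng = np.random.default_rng(14)
        vals = rng.uniform(2.0, 2.9, 1000)
        vals[:380] = 3.0  # 38% at the fit bound
        X = pd.DataFrame({"uAD": vals, "FA": rng.uniform(0.1, 0.6, 1000)})
        rep = screen_metrics(X, {"uAD": 3.0, "FA": 1.0})
        assert "uAD" in rep.discarded and "FA" in rep.retained
        assert rep.ceiling_fraction["uAD"] == pytest.approx(0.38)

    def test_interior_varying_features_retained(self, typing_features):
        X, _ = typing_features
        rep = screen_metrics(X, {"FA": 1.0, "uFA": 1.0, "f_in": 1.0, "RD": 3.0})
        assert rep.retained == list(X.columns)
        assert rep.correlations.shape == (4, 4)

    def test_constant_feature_discarded(self):
        X = pd.DataFrame({"c": np.ones(50), "x": np.linspace(0, 1, 50)})
        rep = screen_metrics(X, {})
        assert "c" in rep.discarded


class TestSelectFeatureSets:
    def test_signal_set_passes_noise_set_fails(self, typing_features):
        X, _ = typing_features
        rng = np.random.default_rng(15)
        X = X.iloc[:400].copy()
        X["noise1"] = rng.standard_normal(len(X))
        X["noise2"] = rng.standard_normal(len(X))
        X["noise3"] = rng.standard_normal(len(X))
        sets = [("FA", "RD", "uFA", "f_in"), ("noise1", "noise2", "noise3")]
        ranked = select_feature_sets(X, candidate_sets=sets, n_splits=20, seed=16)
        best = ranked.iloc[0]
        assert best["features"] == "FA,RD,uFA,f_in" and bool(best["passed"])
        worst = ranked.iloc[-1]
        assert worst["features"] == "noise1,noise2,noise3" and not bool(worst["passed"])

    def test_column_shuffled_data_passes_nothing(self, typing_features):
        X, _ = typing_features
        rng = np.random.default_rng(17)
        Xs = X.iloc[:300].apply(lambda c: rng.permutation(c.to_numpy()))
        ranked = select_feature_sets(
            Xs, candidate_sets=[tuple(X.columns)], n_splits=20, seed=18
        )
        assert not ranked["passed"].any()

    def test_near_identical_sets_agree(self, typing_features):
        X, _ = typing_features
        m1 = kmeans2(X[["FA", "RD", "uFA", "f_in"]], seed=19)
        m2 = kmeans2(X[["FA", "RD", "f_in"]], seed=19)
        l1 = clustering.assign_types(X[["FA", "RD", "uFA", "f_in"]], m1)
        l2 = clustering.assign_types(X[["FA", "RD", "f_in"]], m2)
        assert labeling_agreement(l1, l2) > 0.95

    def test_small_strata_skipped(self, typing_features):
        X, _ = typing_features
        strata = np.array(["big"] * (len(X) - 5) + ["tiny"] * 5)
        ranked = select_feature_sets(
            X, candidate_sets=[tuple(X.columns)], strata=strata,
            n_splits=10, seed=20,
        )
        assert "tiny" in ranked.iloc[0]["skipped_strata"]
        assert "ps_tiny" not in ranked.columns


class TestPatientBurden:
    def test_percentages(self):
        tab = pd.DataFrame(
            {
                "patient_id": ["P1"] * 3,
                "location": ["deep_wm"] * 3,
                "volume_mm3": [100.0, 100.0, 100.0],
                "type": ["B", "B", "A"],
            }
        )
        out = patient_burden(tab)
        row = out[(out["patient_id"] == "P1") & (out["stratum"] == "overall")].iloc[0]
        assert row["percent_B_volume"] == pytest.approx(200 / 3)
        assert row["percent_B_count"] == pytest.approx(200 / 3)

    def test_zero_lesions_missing_not_zero(self):
        tab = pd.DataFrame(
            {"patient_id": ["P1"], "location": ["deep_wm"],
             "volume_mm3": [50.0], "type": ["A"]}
        )
        out = patient_burden(tab, patient_ids=["P1", "P2"])
        row = out[(out["patient_id"] == "P2") & (out["stratum"] == "overall")].iloc[0]
        assert row["count_A"] == 0 and row["count_B"] == 0
        assert np.isnan(row["percent_B_count"]) and np.isnan(row["percent_B_volume"])

    def test_cohort_b_share_near_52_percent(self, typing_features):
        X, is_b = typing_features
        tab = pd.DataFrame(
            {
                "patient_id": "P1",
                "location": "deep_wm",
                "volume_mm3": 1.0,
                "type": np.where(is_b, "B", "A"),
            }
        )
        out = patient_burden(tab)
        row = out[out["stratum"] == "overall"].iloc[0]
        assert row["percent_B_count"] == pytest.approx(52.0, abs=5.0)
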