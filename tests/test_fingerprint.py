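"""Z-scoring, PCA, nearest-centroid clustering, radar and state separation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ictalprint.fingerprint import (
    fit_zscore, apply_zscore, fit_pca, project,
    person_clustering, build_radar, state_separation, binomial_halfwidth,
)

FEATS = [f"f{i}" for i in range(5)]


def table_from(X, person_ids, kind="ictal"):
    df = pd.DataFrame(X, columns=FEATS[: X.shape[1]])
    df.insert(0, "kind", kind)
    df.insert(0, "seizure_id", [f"s{i}" for i in range(len(df))])
    df.insert(0, "person_id", person_ids)
    return df


def gaussian(n, p=5, seed=0, mean=0.0):
    return np.random.default_rng(seed).normal(mean, 1.0, size=(n, p))


class TestZScore:
    def test_fitted_rows_become_standard(self):
        t = table_from(gaussian(40, seed=1), ["A"] * 20 + ["B"] * 20)
        model = fit_zscore(t)
        z = apply_zscore(model, t)
        assert np.allclose(z[FEATS].mean(), 0.0, atol=1e-9)
        assert np.allclose(z[FEATS].std(ddof=1), 1.0, atol=1e-9)

    def test_out_of_sample_rows_not_centered(self):
        t = table_from(gaussian(30, seed=2), ["A"] * 30)
        other = table_from(gaussian(30, seed=3, mean=2.0), ["A"] * 30, kind="preictal")
        z = apply_zscore(fit_zscore(t), other)
        assert np.all(np.abs(z[FEATS].mean()) > 0.5)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            fit_zscore(table_from(gaussian(1), ["A"]))

    def test_constant_feature_named_in_error(self):
        X = gaussian(10, seed=4)
        X[:, 2] = 7.0
        with pytest.raises(ValueError, match="f2"):
            fit_zscore(table_from(X, ["A"] * 10))


class TestPCA:
    def test_isotropic_variance_fractions(self):
        t = table_from(gaussian(4000, seed=5), ["A"] * 4000)
        model = fit_pca(t)
        assert np.allclose(model.explained_variance_ratio, 0.2, atol=0.02)

    def test_planted_axis_alignment(self):
        rng = np.random.default_rng(6)
        axis = np.array([1.0, 0, 0, 0, 0])
        X = rng.normal(size=(300, 5)) * 0.1 + np.outer(rng.normal(size=300), axis)
        model = fit_pca(table_from(X, ["A"] * 300))
        assert abs(np.dot(model.loadings[0], axis)) > 0.99

    def test_orthonormal_loadings_and_reconstruction(self):
        t = table_from(gaussian(50, seed=7), ["A"] * 50)
        model = fit_pca(t)
        assert np.allclose(model.loadings @ model.loadings.T, np.eye(5), atol=1e-8)
        scores = project(model, t)[["PC1", "PC2", "PC3", "PC4", "PC5"]].to_numpy()
        recon = scores @ model.loadings + model.mean
        assert np.allclose(recon, t[FEATS].to_numpy(), atol=1e-8)

    def test_variance_ratios_non_increasing(self):
        model = fit_pca(table_from(gaussian(60, seed=8), ["A"] * 60))
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_sign_convention(self):
        model = fit_pca(table_from(gaussian(60, seed=9), ["A"] * 60))
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_fewer_rows_than_features_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit_pca(table_from(gaussian(4), ["A"] * 4))


class TestPersonClustering:
    def _scores(self, X, pids):
        df = pd.DataFrame(X, columns=["PC1", "PC2", "PC3"])
        df.insert(0, "seizure_id", [f"s{i}" for i in range(len(df))])
        df.insert(0, "person_id", pids)
        return df

    def test_mirrored_clusters_fully_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 1, (20, 3)), rng.normal(3, 1, (20, 3))])
        cset, res = person_clustering(self._scores(X, ["A"] * 20 + ["B"] * 20))
        assert res.accuracy == 1.0
        for pid in ("A", "B"):
            members = X[np.array(["A"] * 20 + ["B"] * 20) == pid]
            assert np.allclose(cset.centroids[pid], members.mean(axis=0), atol=1e-9)

    def test_single_distribution_near_chance(self):
        accs = []
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 3))
            pids = [f"P{i % 4}" for i in range(80)]
            _, res = person_clustering(self._scores(X, pids))
            accs.append(res.accuracy)
        assert abs(np.mean(accs) - 0.25) < 0.15

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(50, 3))
        pids = rng.choice(list("ABCD"), size=50).tolist()
        cset, res = person_clustering(self._scores(X, pids))
        # brute force: exhaustive distance comparison per point
        for i, row in res.assignments.iterrows():
            dists = {p: np.linalg.norm(X[i] - c) for p, c in cset.centroids.items()}
            best = min(dists.values())
            assert dists[row["assigned"]] == pytest.approx(best)

    def test_subset_reproduces_subset_accuracy(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(i * 3, 1, (10, 3)) for i in range(3)])
        pids = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        _, res_all = person_clustering(self._scores(X, pids))
        _, res_sub = person_clustering(self._scores(X, pids), persons=["A", "C"])
        assert set(res_sub.assignments["person_id"]) == {"A", "C"}
        assert res_sub.accuracy >= res_all.accuracy

    def test_leave_one_out_not_higher_than_resubstitution(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(1.0, 1, (15, 3))])
        pids = ["A"] * 15 + ["B"] * 15
        _, res = person_clustering(self._scores(X, pids))
        _, res_loo = person_clustering(self._scores(X, pids), leave_one_out=True)
        assert res_loo.accuracy <= res.accuracy + 1e-9

    def test_single_person_rejected(self):
        with pytest.raises(ValueError, match="2 persons"):
            person_clustering(self._scores(np.zeros((5, 3)), ["A"] * 5))


class TestRadar:
    def test_identical_rows_give_zero_iqr(self):
        X = np.tile([1.0, -2.0, 0.5, 0.0, 3.0], (4, 1))
        radar = build_radar(table_from(X, ["A"] * 4))
        assert np.allclose(radar.median["A"], X[0])
        assert np.allclose(radar.iqr["A"], 0.0)

    def test_hand_percentiles(self):
        X = np.zeros((3, 5))
        X[:, 0] = [-1.0, 0.0, 1.0]
        radar = build_radar(table_from(X, ["A"] * 3))
        assert radar.median["A"][0] == 0.0
        assert radar.iqr["A"][0] == pytest.approx(1.0)

    def test_single_row_person_rejected(self):
        t = table_from(gaussian(3, seed=1), ["A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            build_radar(t)

    def test_frame_export_orders_features(self):
        radar = build_radar(table_from(gaussian(6, seed=2), ["A"] * 3 + ["B"] * 3))
        frame = radar.to_frame()
        assert list(frame[frame["person_id"] == "A"]["feature"]) == FEATS
        assert (frame["iqr"] >= 0).all()


class TestStateSeparation:
    def test_identical_classes_near_half(self):
        X = gaussian(40, seed=1)
        ict = table_from(X, ["A"] * 40)
        other = table_from(X + np.random.default_rng(2).normal(0, 1e-6, X.shape),
                           ["A"] * 40, kind="preictal")
        res = state_separation(ict, other)
        assert abs(res.accuracy - 0.5) < 0.2

    def test_well_separated_classes(self):
        ict = table_from(gaussian(30, seed=3), ["A"] * 30)
        other = table_from(gaussian(30, seed=4, mean=6.0), ["A"] * 30, kind="preictal")
        res = state_separation(ict, other)
        assert res.accuracy == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.ci_halfwidths["accuracy"] == 0.0

    def test_confusion_identities(self):
        rng = np.random.default_rng(5)
        ict = table_from(rng.normal(0, 1, (25, 5)), ["A"] * 25)
        other = table_from(rng.normal(1.0, 1, (30, 5)), ["A"] * 30, kind="baseline")
        res = state_separation(ict, other, other_kind="baseline")
        P, N = res.n["ictal"], res.n["baseline"]
        assert res.sensitivity * P + res.specificity * N == pytest.approx(
            res.accuracy * (P + N))
        assert 0 <= res.accuracy <= 1

    def test_person_missing_one_class_excluded_with_warning(self):
        ict = table_from(gaussian(20, seed=6), ["A"] * 10 + ["B"] * 10)
        other = table_from(gaussian(10, seed=7, mean=3.0), ["A"] * 10, kind="preictal")
        with pytest.warns(UserWarning, match="B"):
            res = state_separation(ict, other)
        assert set(res.assignments["person_id"]) == {"A"}

    def test_distances_exported_per_row(self):
        ict = table_from(gaussian(10, seed=8), ["A"] * 10)
        other = table_from(gaussian(10, seed=9, mean=2.0), ["A"] * 10, kind="preictal")
        res = state_separation(ict, other)
        assert {"dist_ictal", "dist_other", "predicted"} <= set(res.assignments.columns)
        assert len(res.assignments) == 20


class TestBinomialCI:
    def test_wald_closed_form(self):
        # the study's headline separation: p = 0.838, n = 148
        assert binomial_halfwidth(0.838, 148) == pytest.approx(
            1.96 * np.sqrt(0.838 * 0.162 / 148), abs=1e-4)
        assert binomial_halfwidth(0.838, 148) == pytest.approx(0.059, abs=0.0005)

    def test_alternative_methods_reasonable(self):
        for method in ("wilson", "clopper-pearson"):
            hw = binomial_halfwidth(0.8, 100, method=method)
            assert 0.05 < hw < 0.12
        with pytest.raises(ValueError):
            binomial_halfwidth(0.5, 10, method="bogus")
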