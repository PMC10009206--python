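import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from paleotroph import ordination, synthetic_data
from paleotroph.phylo import BMCovariance, bm_covariance


def blobs(seed=0, n=30, delta=4.0, p=2):
    means = {"A": np.zeros(p), "B": np.r_[delta, np.zeros(p - 1)],
             "C": np.r_[0, delta, np.zeros(p - 2)] if p > 1 else np.r_[2 * delta]}
    df = synthetic_data.simulate_class_data(
        ["A", "B", "C"], n, means, np.eye(p), seed=seed)
    return df.drop(columns="label"), df["label"]


class TestPCA:
    def test_perfectly_correlated_variables_give_single_component(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": 3 * x + 1})
        model = ordination.pca_correlation(X)
        assert model.explained[0] == pytest.approx(1.0)

    def test_training_rows_project_onto_their_own_scores(self):
        X, _ = blobs(seed=1, p=3)
        model = ordination.pca_correlation(X)
        np.testing.assert_allclose(model.project(X).to_numpy(),
                                   model.scores.to_numpy(), atol=1e-10)

    def test_score_covariance_is_diagonal_eigenvalues(self):
        X, _ = blobs(seed=2, p=4)
        model = ordination.pca_correlation(X)
        S = np.cov(model.scores.to_numpy(), rowvar=False)
        eigvals = model.explained * 4  # correlation matrix has trace p
        np.testing.assert_allclose(S, np.diag(eigvals), atol=1e-8)

    def test_reconstruction_with_all_components(self):
        X, _ = blobs(seed=3, p=4)
        model = ordination.pca_correlation(X)
        Z = (X.to_numpy() - model.means) / model.sds
        np.testing.assert_allclose(model.scores.to_numpy()
                                   @ model.loadings.T, Z, atol=1e-8)

    def test_loadings_orthonormal(self):
        X, _ = blobs(seed=4, p=5)
        L = ordination.pca_correlation(X).loadings
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)

    def test_extant_centroid_projects_to_origin(self):
        X, _ = blobs(seed=5, p=3)
        model = ordination.pca_correlation(X)
        centroid = pd.DataFrame([X.mean()], columns=X.columns)
        np.testing.assert_allclose(model.project(centroid).to_numpy(), 0,
                                   atol=1e-10)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="b"):
            ordination.pca_correlation(X)

    def test_fossils_never_change_the_fit(self):
        X, _ = blobs(seed=6)
        model = ordination.pca_correlation(X)
        fossil = pd.DataFrame([[10.0, -5.0]], columns=X.columns,
                              index=["fossil"])
        refit = ordination.pca_correlation(X)  # fossils simply not passed
        np.testing.assert_array_equal(model.loadings, refit.loadings)
        assert model.project(fossil).shape == (1, 2)


class TestFDA:
    def test_separable_blobs_classified_perfectly(self):
        X, labels = blobs(seed=7, delta=10.0)
        model = ordination.fda_fit(X, labels)
        pred = ordination.discriminant_predict(model, X)
        assert (pred["predicted"] == labels).all()

    def test_axes_bounded_by_classes_minus_one(self):
        X, labels = blobs(seed=8, p=6)
        assert ordination.fda_fit(X, labels).n_axes <= 2

    def test_agreement_with_lda_oracle(self):
        """Shared-covariance Gaussians: FDA should reproduce LDA."""
        rng = np.random.default_rng(9)
        cov = np.array([[2.0, 0.6, 0], [0.6, 1.0, 0.2], [0, 0.2, 1.5]])
        means = {"A": [0, 0, 0], "B": [1.5, 0.5, 0], "C": [0, 1.5, 1.0]}
        df = synthetic_data.simulate_class_data(
            ["A", "B", "C"], 167, means, cov, seed=10)
        X, labels = df.drop(columns="label"), df["label"]
        model = ordination.fda_fit(X, labels)
        pred = ordination.discriminant_predict(model, X)["predicted"]
        lda = LinearDiscriminantAnalysis().fit(X, labels)
        assert (pred.to_numpy() == lda.predict(X)).mean() >= 0.98

    def test_small_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="B"):
            ordination.fda_fit(X, ["A", "A", "A", "A", "B"])

    def test_posteriors_sum_to_one(self):
        X, labels = blobs(seed=11)
        model = ordination.fda_fit(X, labels)
        new = pd.DataFrame(np.random.default_rng(1).normal(0, 5, (20, 2)),
                           columns=X.columns)
        post = ordination.discriminant_predict(model, new)
        np.testing.assert_allclose(
            post[model.classes].sum(axis=1), 1.0, atol=1e-9)

    def test_centroid_point_assigned_to_its_class(self):
        X, labels = blobs(seed=12, delta=6.0)
        model = ordination.fda_fit(X, labels, priors="equal")
        for k, cls in enumerate(model.classes):
            x = X[(labels == cls).to_numpy()].mean()
            post = ordination.discriminant_predict(
                model, pd.DataFrame([x], columns=X.columns))
            assert post["predicted"].iloc[0] == cls

    def test_doubling_a_prior_increases_its_posterior(self):
        X, labels = blobs(seed=13)
        base = ordination.fda_fit(X, labels, priors="equal")
        boosted = ordination.fda_fit(
            X, labels, priors={"A": 2.0, "B": 1.0, "C": 1.0})
        pts = pd.DataFrame(np.random.default_rng(2).normal(1, 2, (10, 2)),
                           columns=X.columns)
        pa = ordination.discriminant_predict(base, pts)["A"]
        pb = ordination.discriminant_predict(boosted, pts)["A"]
        assert (pb > pa).all()

    def test_prediction_invariant_to_variable_reordering(self):
        X, labels = blobs(seed=14, p=4)
        m1 = ordination.fda_fit(X, labels)
        cols = list(X.columns)[::-1]
        m2 = ordination.fda_fit(X[cols], labels)
        pts = pd.DataFrame(np.random.default_rng(3).normal(size=(15, 4)),
                           columns=X.columns)
        p1 = ordination.discriminant_predict(m1, pts)[m1.classes]
        p2 = ordination.discriminant_predict(m2, pts)[m2.classes]
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)


class TestPFDA:
    def _tree_data(self, seed=20, n=60, delta=3.0):
        tree = synthetic_data.random_coalescent_tree(n, seed=seed)
        C = bm_covariance(tree)
        df = synthetic_data.simulate_class_data(
            ["A", "B", "C"], n // 3,
            {"A": [0, 0], "B": [delta, 0], "C": [0, delta]},
            np.eye(2), seed=seed + 1)
        X = df.drop(columns="label").set_axis(C.taxon_order, axis=0)
        labels = pd.Series(df["label"].to_numpy(), index=C.taxon_order)
        return X, labels, C

    def test_lambda_zero_on_ultrametric_tree_matches_fda(self):
        X, labels, C = self._tree_data()
        fda = ordination.fda_fit(X, labels)
        pfda = ordination.pfda_fit(X, labels, C, lam=0.0)
        pts = pd.DataFrame(np.random.default_rng(4).normal(0, 2, (10, 2)),
                           columns=X.columns)
        np.testing.assert_allclose(
            ordination.discriminant_predict(fda, pts)[fda.classes],
            ordination.discriminant_predict(pfda, pts)[pfda.classes],
            atol=1e-9)

    def test_identity_covariance_matches_fda_bitwise(self):
        X, labels, _ = self._tree_data(seed=21)
        C = BMCovariance(list(X.index), np.eye(len(X)))
        fda = ordination.fda_fit(X, labels)
        pfda = ordination.pfda_fit(X, labels, C, lam=1.0)
        pts = pd.DataFrame(np.random.default_rng(5).normal(size=(6, 2)),
                           columns=X.columns)
        np.testing.assert_array_equal(
            ordination.discriminant_predict(fda, pts)[fda.classes].to_numpy(),
            ordination.discriminant_predict(pfda, pts)[pfda.classes].to_numpy())

    def test_lambda_one_uses_full_covariance(self):
        X, labels, C = self._tree_data(seed=22)
        pfda = ordination.pfda_fit(X, labels, C, lam=1.0)
        assert pfda.lam == 1.0
        Cl = C.matrix / np.diag(C.matrix).mean()
        np.testing.assert_allclose(
            pfda.whitener @ pfda.whitener, np.linalg.inv(Cl), atol=1e-6)

    def test_fossil_rows_rejected_from_fitting(self):
        X, labels, C = self._tree_data(seed=23)
        X2 = pd.concat([X, pd.DataFrame([[0.0, 0.0]], columns=X.columns,
                                        index=["fossil_1"])])
        labels2 = pd.concat([labels, pd.Series({"fossil_1": "A"})])
        with pytest.raises(ValueError, match="fossil"):
            ordination.pfda_fit(X2, labels2, C, lam=1.0)

    def test_invalid_lambda_rejected(self):
        X, labels, C = self._tree_data(seed=24)
        with pytest.raises(ValueError, match="lambda"):
            ordination.pfda_fit(X, labels, C, lam=1.5)


class TestOptimalLambda:
    def test_single_value_grid_returns_it(self, random_tree_32_cov):
        X = pd.DataFrame(np.random.default_rng(6).normal(size=(32, 2)),
                         index=random_tree_32_cov.taxon_order)
        assert ordination.optimal_lambda(X, random_tree_32_cov,
                                         grid=[0.37]) == 0.37

    @pytest.mark.parametrize("lam_true,accept", [(0.0, lambda l: l <= 0.3),
                                                 (1.0, lambda l: l >= 0.7)])
    def test_lambda_recovery(self, lam_true, accept):
        """Recovery at the ends of the scale succeeds in >= 80% of runs."""
        tree = synthetic_data.random_coalescent_tree(32, seed=100)
        C = bm_covariance(tree)
        grid = np.round(np.arange(0, 1.01, 0.05), 2)
        hits = 0
        for rep in range(100):
            Y = synthetic_data.simulate_bm_traits(
                tree, p=3, lambda_true=lam_true, seed=1000 + rep)
            hits += accept(ordination.optimal_lambda(Y, C, grid=grid))
        assert hits >= 80
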