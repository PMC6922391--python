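import json

import numpy as np
import pandas as pd
import pytest
from oracles import qp_dual_oracle

import yawndyn as yd
from yawndyn.svm import MODEL_A, MODEL_B, GridSpec, ModelSpec, SVMError


def to_labels(y_sign):
    return ["yawn" if v > 0 else "non_yawn" for v in y_sign]


class TestFeatureMatrix:
    def test_model_b_row(self):
        feats = pd.DataFrame(
            {
                "total_duration": [5.1],
                "plateau_duration": [2.1],
                "asymmetry": [1.0],
            },
            index=["e1"],
        )
        X, ids = yd.feature_matrix(feats, MODEL_B)
        assert ids == ["e1"]
        np.testing.assert_allclose(X, [[5.1, 2.1, 1.0]])

    def test_product_term_column(self):
        feats = pd.DataFrame(
            {"total_duration": [5.1], "plateau_duration": [2.1], "asymmetry": [1.0]},
            index=["e1"],
        )
        spec = ModelSpec("B", MODEL_B.features, interaction_mode="add_product_term")
        X, _ = yd.feature_matrix(feats, spec)
        assert X.shape == (1, 4)
        assert X[0, -1] == pytest.approx(5.1 * 2.1 * 1.0)

    def test_study_sized_matrix_shape(self, study_features):
        X, ids = yd.feature_matrix(study_features, MODEL_A)
        assert X.shape == (130, 5)
        assert len(ids) == 130

    def test_nonfinite_row_rejected_by_name(self, study_features):
        feats = study_features.copy()
        feats.loc[feats.index[3], "oc_ratio"] = np.nan
        with pytest.raises(SVMError, match=feats.index[3]):
            yd.feature_matrix(feats, MODEL_A)


class TestScaling:
    def test_simple_column(self):
        params = yd.fit_scaling(np.array([[1.0], [2.0], [3.0]]))
        Z = yd.apply_scaling(np.array([[1.0], [2.0], [3.0]]), params)
        np.testing.assert_allclose(Z.ravel(), [-1, 0, 1])
        assert params.scale[0] == pytest.approx(1.0)  # n-1 denominator

    def test_identity_on_standardized_data(self, rng):
        X = rng.normal(size=(50, 3))
        params = yd.fit_scaling(X)
        Z = yd.apply_scaling(X, params)
        Z2 = yd.apply_scaling(Z, yd.fit_scaling(Z))
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_train_fitted_scaling_differs_from_pooled(self, rng):
        """Scaling fitted on the training rows and applied to a shifted
        test set must differ from scaling refitted on the pooled data —
        the guard against train/test leakage."""
        train = rng.normal(0, 1, size=(40, 2))
        test = rng.normal(5, 1, size=(20, 2))  # shifted distribution
        p_train = yd.fit_scaling(train)
        p_pooled = yd.fit_scaling(np.vstack([train, test]))
        z_honest = yd.apply_scaling(test, p_train)
        z_leaky = yd.apply_scaling(test, p_pooled)
        assert np.abs(z_honest - z_leaky).max() > 1.0

    def test_constant_column_dropped_with_warning(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            params = yd.fit_scaling(X)
        assert params.kept.tolist() == [True, False]
        assert yd.apply_scaling(X, params).shape == (3, 1)


class TestTrainPredict:
    def test_symmetric_pair_midpoint_is_boundary(self):
        X = np.array([[0.0], [2.0]])
        model = yd.train_svm(X, ["non_yawn", "yawn"], C=1e3, gamma=1.0, scale=False)
        labels, f = yd.predict(model, X)
        assert labels == ["non_yawn", "yawn"]
        _, f_mid = yd.predict(model, np.array([[1.0]]))
        assert f_mid[0] == pytest.approx(0.0, abs=1e-6)

    def test_xor_layout_separated_by_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = ["yawn", "yawn", "non_yawn", "non_yawn"]
        model = yd.train_svm(X, y, C=100.0, gamma=1.0, scale=False)
        labels, _ = yd.predict(model, X)
        assert labels == y

    def test_single_class_rejected(self):
        with pytest.raises(SVMError, match="both classes"):
            yd.train_svm(np.eye(3), ["yawn"] * 3, C=1.0, gamma=1.0)

    def test_empty_prediction(self, study_features):
        X, _ = yd.feature_matrix(study_features, MODEL_B)
        model = yd.train_svm(X, study_features["label_ref"], C=10, gamma=1)
        labels, f = yd.predict(model, np.empty((0, 3)))
        assert labels == [] and len(f) == 0

    def test_dimension_mismatch_rejected(self, study_features):
        X, _ = yd.feature_matrix(study_features, MODEL_B)
        model = yd.train_svm(X, study_features["label_ref"], C=10, gamma=1)
        with pytest.raises(SVMError, match="dimension"):
            yd.predict(model, np.zeros((2, 5)))

    def test_json_round_trip_preserves_decisions(self, study_features):
        X, _ = yd.feature_matrix(study_features, MODEL_A)
        model = yd.train_svm(X, study_features["label_ref"], C=100, gamma=0.1, spec=MODEL_A)
        text = model.to_json()
        back = yd.SVMModel.from_json(text)
        np.testing.assert_allclose(
            model.decision_function(X), back.decision_function(X), rtol=0, atol=1e-12
        )
        assert json.loads(text)["spec"]["name"] == "A"


class TestDualSolution:
    def make_instance(self, rng, n=8, C=10.0, gamma=0.5):
        X = rng.normal(size=(n, 2))
        y_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        if len(set(y_sign)) < 2:
            y_sign[0] = -y_sign[0]
        return X, y_sign, C, gamma

    def test_dual_objective_matches_qp_oracle(self, rng):
        """On small instances the libsvm solution's dual objective agrees
        with an independent generic QP solve to 1e-4 relative."""
        for _ in range(10):
            X, y_sign, C, gamma = self.make_instance(rng)
            model = yd.train_svm(X, to_labels(y_sign), C=C, gamma=gamma, scale=False)
            ours = model.dual_objective()
            oracle = qp_dual_oracle(X, y_sign, C, gamma)
            assert ours == pytest.approx(oracle, rel=1e-4, abs=1e-6)

    def test_kkt_feasibility_on_every_fit(self, rng):
        """Dual feasibility: 0 < alpha <= C for stored support vectors and
        sum(alpha_i y_i) = 0 within tolerance."""
        for _ in range(10):
            X, y_sign, C, gamma = self.make_instance(rng, n=12)
            model = yd.train_svm(X, to_labels(y_sign), C=C, gamma=gamma, scale=False)
            alpha = np.abs(model.dual_coef)
            assert (alpha > 0).all()
            assert (alpha <= C + 1e-8).all()
            assert abs(model.dual_coef.sum()) < 1e-6

    def test_free_support_vectors_sit_on_the_margin(self, rng):
        X, y_sign, C, gamma = self.make_instance(rng, n=20, C=5.0)
        model = yd.train_svm(X, to_labels(y_sign), C=C, gamma=gamma, scale=False)
        f_sv = model.decision_function(model.support_vectors, scale=False)
        alpha = np.abs(model.dual_coef)
        free = alpha < C - 1e-6
        if free.any():
            np.testing.assert_allclose(np.abs(f_sv[free]), 1.0, atol=1e-3)

    def test_objective_nondecreasing_in_C(self, rng):
        X, y_sign, _, gamma = self.make_instance(rng, n=15)
        objs = [
            yd.train_svm(X, to_labels(y_sign), C=C, gamma=gamma, scale=False).dual_objective()
            for C in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(b >= a - 1e-8 for a, b in zip(objs, objs[1:]))

    def test_prediction_invariance_under_prescaling(self, study_features):
        """A model fitted with internal scaling equals a scale-free fit on
        externally standardized features."""
        X, _ = yd.feature_matrix(study_features, MODEL_B)
        y = study_features["label_ref"]
        m1 = yd.train_svm(X, y, C=10, gamma=1, scale=True)
        Z = yd.apply_scaling(X, yd.fit_scaling(X))
        m2 = yd.train_svm(Z, y, C=10, gamma=1, scale=False)
        np.testing.assert_allclose(
            m1.decision_function(X), m2.decision_function(Z), atol=1e-8
        )


class TestGridSearch:
    def test_single_cell_grid(self, study_features):
        X, _ = yd.feature_matrix(study_features, MODEL_B)
        res = yd.grid_search_cv(
            X,
            study_features["label_ref"],
            GridSpec(C_values=(10.0,), gamma_values=(1.0,), seed=1),
        )
        assert (res.best_C, res.best_gamma) == (10.0, 1.0)
        assert res.cv_error.shape == (1, 1)

    def test_tie_break_prefers_smallest_C_then_gamma(self):
        """On a widely separated two-cluster dataset many grid cells reach
        zero CV error; the reported optimum is the smallest such C, then
        the smallest gamma."""
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = ["non_yawn"] * 20 + ["yawn"] * 20
        res = yd.grid_search_cv(X, y, GridSpec(folds=5, seed=2))
        zero_cells = [
            (C, g)
            for C in res.cv_error.index
            for g in res.cv_error.columns
            if res.cv_error.loc[C, g] == 0
        ]
        assert (res.best_C, res.best_gamma) == min(zero_cells)

    def test_bit_reproducible_for_fixed_seed(self, study_features):
        X, _ = yd.feature_matrix(study_features, MODEL_B)
        y = study_features["label_ref"]
        grid = GridSpec(C_values=(1.0, 10.0), gamma_values=(0.1, 1.0), folds=5, seed=11)
        r1 = yd.grid_search_cv(X, y, grid)
        r2 = yd.grid_search_cv(X, y, grid)
        pd.testing.assert_frame_equal(r1.cv_error, r2.cv_error, check_exact=True)
        assert (r1.best_C, r1.best_gamma) == (r2.best_C, r2.best_gamma)

    def test_folds_reduced_when_minority_class_small(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = ["yawn"] * 4 + ["non_yawn"] * 16
        with pytest.warns(UserWarning, match="reducing folds"):
            res = yd.grid_search_cv(
                X, y, GridSpec(C_values=(1.0,), gamma_values=(1.0,), folds=10, seed=0)
            )
        assert res.folds_used == 4
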