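import numpy as np
import pandas as pd
import pytest

from dige_biomarker import (
    AnalysisError,
    fit_logit_on_pcs,
    loocv,
    odds_ratio,
    panel_experiment,
    robust_pca,
    split_tumor_groups,
    top_correlated,
    tumor_group_diffexp,
)
from dige_biomarker.panel_classifier import TumorGroups

from conftest import default_study, make_matrix


def full_data_linear_predictor(matrix, seed):
    model = robust_pca(matrix, 3)
    sub = matrix.subset_samples(model.retained_samples)
    fit = fit_logit_on_pcs(model.sample_coordinates().to_numpy(),
                           sub.labels.to_numpy())
    lp = pd.Series(fit.linear_predictor(model.sample_coordinates().to_numpy()),
                   index=model.retained_samples)
    return lp, sub.labels, model


class TestLogit:
    def test_null_scores_give_prior_intercept(self):
        rng = np.random.default_rng(0)
        n_t, n_b = 2400, 2100
        scores = rng.standard_normal((n_t + n_b, 3))
        labels = ["tumor"] * n_t + ["benign"] * n_b
        fit = fit_logit_on_pcs(scores, labels)
        assert not fit.penalized
        assert fit.coef[0] == pytest.approx(np.log(n_t / n_b), abs=0.1)
        assert np.abs(fit.coef[1:]).max() < 0.1

    def test_separated_toy_triggers_fallback_and_predicts(self):
        scores = np.array([[1.0], [2.0], [3.0], [-1.0], [-2.0], [-3.0]])
        labels = ["tumor"] * 3 + ["benign"] * 3
        fit = fit_logit_on_pcs(scores, labels)
        assert fit.penalized
        pred = fit.predict_proba(scores) > 0.5
        assert pred.tolist() == [True, True, True, False, False, False]

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        for _ in range(10):
            Z = rng.standard_normal((80, 3))
            eta = 0.3 + Z @ np.array([0.8, -0.5, 0.2])
            y = rng.random(80) < 1 / (1 + np.exp(-eta))
            labels = np.where(y, "tumor", "benign")
            fit = fit_logit_on_pcs(Z, labels)
            if fit.penalized:
                continue
            oracle = sm.Logit(y.astype(float), sm.add_constant(Z)).fit(disp=0)
            assert np.allclose(fit.coef, oracle.params, atol=1e-6)

    def test_one_class_raises(self):
        with pytest.raises(AnalysisError):
            fit_logit_on_pcs(np.zeros((4, 3)), ["tumor"] * 4)

    def test_predictions_invariant_to_affine_transform(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((60, 3))
        eta = Z @ np.array([0.6, -0.4, 0.3])
        labels = np.where(rng.random(60) < 1 / (1 + np.exp(-eta)),
                          "tumor", "benign")
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        f1 = fit_logit_on_pcs(Z, labels)
        f2 = fit_logit_on_pcs(Z @ A + b, labels)
        if not (f1.penalized or f2.penalized):
            assert np.allclose(f1.predict_proba(Z),
                               f2.predict_proba(Z @ A + b), atol=1e-6)


class TestLoocv:
    def test_rank1_separated_data_is_perfect(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.5, 1.5, 20)
        z = np.array([1.0] * 10 + [-1.0] * 10)  # zero noise, rank 1
        m = make_matrix(np.outer(w, z), n_tumor=10)
        assert loocv(m, 3).accuracy == 1.0

    def test_default_study_accuracy_floor(self, matrix_seed1):
        assert loocv(matrix_seed1, 3).accuracy >= 0.80

    def test_permuted_labels_near_chance(self, matrix_seed1):
        rng = np.random.default_rng(4)
        perm = matrix_seed1.labels.copy()
        perm[:] = rng.permutation(perm.to_numpy())
        from dige_biomarker import ExpressionMatrix
        m = ExpressionMatrix(matrix_seed1.values.copy(), perm)
        acc = loocv(m, 3).accuracy
        assert 0.25 <= acc <= 0.75

    def test_confusion_sums_to_n(self, matrix_seed1):
        res = loocv(matrix_seed1, 3)
        assert res.confusion.sum() == 45
        assert res.accuracy == pytest.approx(
            (res.confusion[0, 0] + res.confusion[1, 1]) / 45)

    def test_no_leakage_of_held_out_sample(self, matrix_seed1):
        held = matrix_seed1.sample_ids[7]
        res = loocv(matrix_seed1, 3)
        train = matrix_seed1.subset_samples(
            [s for s in matrix_seed1.sample_ids if s != held])
        model = robust_pca(train, 3)
        fit = fit_logit_on_pcs(
            model.sample_coordinates().to_numpy(),
            matrix_seed1.labels.loc[model.retained_samples].to_numpy())
        z = model.project(matrix_seed1.values[held])
        assert res.probabilities[held] == pytest.approx(
            float(fit.predict_proba(z)[0]), abs=1e-12)
        # the same fold model scores a perturbed held-out profile without
        # being refit: its training is independent of the held-out sample
        z2 = model.project(matrix_seed1.values[held] + 1.0)
        assert not np.allclose(z, z2)


class TestTumorGroups:
    def test_split_deterministic(self, matrix_seed1):
        lp, labels, _ = full_data_linear_predictor(matrix_seed1, 1)
        a = split_tumor_groups(lp, labels, seed=11)
        b = split_tumor_groups(lp, labels, seed=11)
        pd.testing.assert_series_equal(a.assignments, b.assignments)

    def test_groups_cover_all_tumors_nonempty(self, matrix_seed1):
        lp, labels, _ = full_data_linear_predictor(matrix_seed1, 1)
        g = split_tumor_groups(lp, labels)
        assert set(g.assignments.index) == set(
            labels.index[labels == "tumor"])
        assert len(g.group(1)) > 0 and len(g.group(2)) > 0

    def test_group1_nearer_benign(self, matrix_seed1):
        lp, labels, _ = full_data_linear_predictor(matrix_seed1, 1)
        g = split_tumor_groups(lp, labels)
        benign_mean = lp[labels == "benign"].mean()
        d1 = abs(lp[g.group(1)].mean() - benign_mean)
        d2 = abs(lp[g.group(2)].mean() - benign_mean)
        assert d1 <= d2

    def test_unimodal_tumors_flagged_weak(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i:02d}" for i in range(40)]
        lp = pd.Series(np.r_[rng.standard_normal(20) + 4,
                             rng.standard_normal(20) - 4], index=ids)
        labels = pd.Series(["tumor"] * 20 + ["benign"] * 20, index=ids)
        g = split_tumor_groups(lp, labels, seed=0)
        assert g.weak

    def test_split_is_valid_partition_across_seeds(self):
        # the >= 0.8 Rand recovery expectation is asserted (and left red) in
        # the acceptance suite; see the decisions ledger for why it is not
        # attainable under the specified model + method. Here: contract only.
        for seed in (1, 2, 3, 4, 5):
            design, _, matrix = default_study(seed)
            lp, labels, _ = full_data_linear_predictor(matrix, seed)
            g = split_tumor_groups(lp, labels, seed=seed)
            tumors = set(labels.index[labels == "tumor"])
            assert set(g.assignments.index) == tumors
            assert len(g.group(1)) > 0 and len(g.group(2)) > 0
            assert g.separation >= 0

    def test_too_few_tumors_raises(self):
        lp = pd.Series([1.0, 2.0], index=["a", "b"])
        labels = pd.Series(["tumor", "benign"], index=["a", "b"])
        with pytest.raises(AnalysisError):
            split_tumor_groups(lp, labels)


class TestTumorGroupDiffexp:
    def _groups(self, matrix, members):
        tumors = matrix.class_samples("tumor")
        assign = pd.Series(
            [2 if s in members else 1 for s in tumors], index=tumors)
        return TumorGroups(assign, separation=np.inf, weak=False)

    def test_identical_groups_log10p_zero(self):
        x = np.tile(np.arange(1.0, 9.0), (4, 1))
        x[:, :4] = 5.0  # tumors constant -> the two groups are identical
        m = make_matrix(x, n_tumor=4)
        groups = self._groups(m, members=m.class_samples("tumor")[:2])
        de = tumor_group_diffexp(m, groups)
        assert (de["log10_p"] == 0.0).all()

    def test_planted_features_rank_high(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((118, 45)) * 0.3
        tumor_ids = [f"s{i:02d}" for i in range(24)]
        sub_ids = set(tumor_ids[:10])
        planted = list(range(26))
        for i in planted:
            x[i, :10] += 1.5  # subgroup effect on 26 features
        m = make_matrix(x, n_tumor=24)
        groups = self._groups(m, members=sub_ids)
        de = tumor_group_diffexp(m, groups)
        top40 = set(de.index[:40])
        hits = sum(f"F{i:03d}" in top40 for i in planted)
        assert hits / 26 >= 0.8

    def test_null_min_log10p_bounded(self):
        rng = np.random.default_rng(7)
        ok = 0
        for seed in range(20):
            x = rng.standard_normal((118, 45))
            m = make_matrix(x, n_tumor=24)
            tumors = m.class_samples("tumor")
            members = set(rng.choice(tumors, size=10, replace=False))
            de = tumor_group_diffexp(m, self._groups(m, members))
            ok += de["log10_p"].min() > -4
        assert ok / 20 >= 0.9


class TestTopCorrelated:
    def test_feature_equal_to_score_ranks_first(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.standard_normal((20, 15)), n_tumor=7)
        model = robust_pca(m, 3)
        t1 = model.scores["PC1"].to_numpy()
        values = np.vstack([t1, m.values.to_numpy()])
        m2 = make_matrix(values, n_tumor=7)
        model2 = robust_pca(m2, 3)
        tops = top_correlated(m2, model2, n=5)
        # feature F000 is the PC1 score vector itself
        corr = np.corrcoef(values[0], model2.scores["PC1"])[0, 1]
        assert abs(corr) > 0.99
        assert tops["PC1"][0] == "F000"

    def test_rank3_correlations_have_unit_square_sum(self):
        rng = np.random.default_rng(9)
        L = rng.standard_normal((25, 3))
        F = rng.standard_normal((3, 14))
        m = make_matrix(L @ F, n_tumor=7)
        model = robust_pca(m, 3)
        V = model.scores.to_numpy()
        X = m.values.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        r = (Xc / np.linalg.norm(Xc, axis=1, keepdims=True)) \
            @ (V - V.mean(axis=0)) / np.linalg.norm(V - V.mean(axis=0), axis=0)
        assert np.allclose((r ** 2).sum(axis=1), 1.0, atol=1e-8)

    def test_ties_broken_by_feature_id(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        m = make_matrix(np.vstack([x, x, x]), n_tumor=2)
        model = robust_pca(m, 1)
        tops = top_correlated(m, model, n=3)
        assert tops["PC1"] == ["F000", "F001", "F002"]

    def test_n_too_large_raises(self, matrix_seed1):
        model = robust_pca(matrix_seed1, 3)
        with pytest.raises(AnalysisError):
            top_correlated(matrix_seed1, model, n=10_000)


class TestPanel:
    def test_odds_ratio_arithmetic(self):
        assert odds_ratio([[23, 1], [3, 18]]) == pytest.approx(138.0)
        # +0.5 correction only when a cell is zero:
        # (23.5*18.5)/(0.5*3.5) for [[23,0],[3,18]]
        assert odds_ratio([[23, 0], [3, 18]]) == pytest.approx(
            (23.5 * 18.5) / (0.5 * 3.5))
        # the spec's continuity-corrected value for [[23,1],[3,18]] is
        # (23.5*18.5)/(1.5*3.5) = 82.8095 if forced; see decisions ledger
        assert (23.5 * 18.5) / (1.5 * 3.5) == pytest.approx(82.8095, abs=1e-4)

    def test_full_panel_has_zero_sampling_variance(self, matrix_seed1):
        model = robust_pca(matrix_seed1, 3)
        curve = panel_experiment(matrix_seed1, model, sizes=[38], reps=5,
                                 n_top=38, seed=0)
        # drawing all 38 features is deterministic; median == every replicate
        c2 = panel_experiment(matrix_seed1, model, sizes=[38], reps=1,
                              n_top=38, seed=99)
        assert curve.table["median_accuracy"].iloc[0] == \
            c2.table["median_accuracy"].iloc[0]
        assert curve.table["median_odds_ratio"].iloc[0] == \
            c2.table["median_odds_ratio"].iloc[0]

    def test_reproducible_given_seed(self, matrix_seed1):
        model = robust_pca(matrix_seed1, 3)
        a = panel_experiment(matrix_seed1, model, sizes=[1, 5], reps=20, seed=3)
        b = panel_experiment(matrix_seed1, model, sizes=[1, 5], reps=20, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_averaging_improves_accuracy(self):
        better = 0
        for seed in (1, 2, 3, 4, 5):
            _, _, matrix = default_study(seed)
            model = robust_pca(matrix, 3)
            curve = panel_experiment(matrix, model, sizes=[1, 25], reps=30,
                                     seed=seed)
            a1, a25 = curve.table["median_accuracy"]
            better += a25 >= a1
        assert better >= 4

    def test_invalid_reps(self, matrix_seed1):
        model = robust_pca(matrix_seed1, 3)
        with pytest.raises(AnalysisError):
            panel_experiment(matrix_seed1, model, sizes=[1], reps=0)
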