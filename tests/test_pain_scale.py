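"""Scoring core: composite score, z-scores, PC1, SVM probability, von Frey."""

import itertools

import numpy as np
import pandas as pd
import pytest

from painscale.errors import (
    AmbiguityError,
    DegenerateFeatureError,
    InputError,
)
from painscale.pain_scale import (
    apply_zscore,
    composite_score,
    composite_scores,
    feature_matrix,
    fit_pc1,
    fit_scale,
    fit_zscore,
    percent_response_at_10g,
    predict_pain_probability,
    project_pc1,
    score_trials,
    train_svm,
    vfh_threshold,
)
from painscale.synthetic_data import default_config, generate_cohort
from painscale.trial_model import Behaviors


def pc1_oracle(z):
    """Independent brute-force leading eigenvector: explicit covariance sums
    plus power iteration (no numpy.linalg eigendecomposition)."""
    z = np.asarray(z, float)
    n, p = z.shape
    mu = z.sum(axis=0) / n
    cov = np.zeros((p, p))
    for i in range(n):
        d = z[i] - mu
        cov += np.outer(d, d)
    cov /= n - 1
    v = np.ones(p) / np.sqrt(p)
    for _ in range(5000):
        w = cov @ v
        nw = np.sqrt((w**2).sum())
        if nw == 0:
            return v
        w /= nw
        if np.abs(w @ v) > 1 - 1e-15:
            v = w
            break
        v = w
    return v


class TestCompositeScore:
    @pytest.mark.parametrize("combo", list(itertools.product((0, 1), repeat=4)))
    def test_equals_sum_of_binaries_all_16(self, combo):
        assert composite_score(Behaviors(*combo)) == sum(combo)

    def test_vectorized_matches_and_bounds(self, scored_baseline):
        df = scored_baseline
        assert df["composite_score"].between(0, 4).all()
        assert (df["composite_score"] == df[["orbital_tightening", "paw_shake", "jump", "paw_guard"]].sum(axis=1)).all()


class TestZScore:
    def test_analytic_1_2_3(self):
        X = np.array([[1.0], [2.0], [3.0]])
        p = fit_zscore(X, feature_names=("f",))
        assert p.means[0] == 2.0 and p.sds[0] == 1.0
        assert apply_zscore(p, X).ravel().tolist() == [-1.0, 0.0, 1.0]

    def test_mean_row_maps_to_zero_and_2sd_to_2(self, rng):
        X = rng.normal(10, 3, size=(50, 3))
        p = fit_zscore(X)
        assert np.allclose(apply_zscore(p, p.means[None, :]), 0.0, atol=1e-12)
        assert np.allclose(apply_zscore(p, (p.means + 2 * p.sds)[None, :]), 2.0, atol=1e-12)

    def test_training_features_standardized(self, rng):
        X = rng.lognormal(1, 0.5, size=(200, 3))
        Z = apply_zscore(fit_zscore(X), X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_names_feature(self):
        X = np.column_stack([np.arange(5.0), np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateFeatureError, match="paw_speed"):
            fit_zscore(X)


class TestPC1:
    def test_two_identical_columns_one_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        z = np.column_stack([a, a, np.zeros(40)])
        labels = np.array(["CS"] * 20 + ["HP"] * 20)
        z[20:, :2] += 2.0  # HP trials higher so orientation is defined
        v, _ = fit_pc1(z, labels)
        assert np.allclose(np.abs(v), [1 / np.sqrt(2), 1 / np.sqrt(2), 0], atol=1e-9)
        assert np.array([1.0, 1.0, 0.0]) @ v == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_unit_norm_and_orientation(self, rng):
        z = rng.normal(size=(60, 3))
        labels = np.array(["CS"] * 30 + ["HP"] * 30)
        z[30:] += [1.5, 1.0, 0.5]
        v, explained = fit_pc1(z, labels)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
        scores = z @ v
        assert scores[30:].mean() > scores[:30].mean()
        assert 0 < explained <= 1

    def test_matches_power_iteration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 40))
            z = rng.normal(size=(n, 3)) * rng.uniform(0.5, 3.0, size=3)
            labels = np.array(["CS"] * (n // 2) + ["HP"] * (n - n // 2))
            z[n // 2 :] += rng.uniform(0.5, 2.0)
            v, _ = fit_pc1(z, labels)
            w = pc1_oracle(z)
            assert abs(v @ w) > 1 - 1e-9

    def test_tied_eigenvalues_are_ambiguous(self):
        # isotropic covariance: leading eigenvalues tie
        z = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        labels = np.array(["CS", "CS", "CS", "HP", "HP", "HP"])
        with pytest.raises(AmbiguityError):
            fit_pc1(z, labels)

    def test_requires_both_classes(self, rng):
        z = rng.normal(size=(10, 3))
        with pytest.raises(InputError):
            fit_pc1(z, np.array(["CS"] * 10))


class TestProjection:
    def test_training_scores_reproduced_exactly(self, baseline_cohort, fitted_model, scored_baseline):
        trials, _ = baseline_cohort
        again = score_trials(fitted_model, trials)
        assert np.array_equal(again["pc1_score"].to_numpy(), scored_baseline["pc1_score"].to_numpy())

    def test_mean_row_scores_zero_and_unit_shift_scores_one(self, fitted_model):
        m = fitted_model
        assert project_pc1(m, m.zscore_means[None, :])[0] == pytest.approx(0.0, abs=1e-12)
        row = m.zscore_means + m.pc1_loadings * m.zscore_sds
        assert project_pc1(m, row[None, :])[0] == pytest.approx(1.0, abs=1e-9)

    def test_appending_trials_never_changes_old_scores(self, baseline_cohort, fitted_model):
        trials, _ = baseline_cohort
        extra, _ = generate_cohort(default_config("vfh", seed=99))
        combined = pd.concat([trials, extra], ignore_index=True)
        s_old = score_trials(fitted_model, trials)["pc1_score"].to_numpy()
        s_comb = score_trials(fitted_model, combined)["pc1_score"].to_numpy()[: len(trials)]
        assert np.array_equal(s_old, s_comb)


class TestSvmProbability:
    def test_symmetric_classes_give_half_at_zero(self, rng):
        neg = -1.0 + 0.1 * rng.standard_normal(20)
        pos = -neg
        scores = np.concatenate([neg, pos])
        y = np.array([0] * 20 + [1] * 20)
        svm = train_svm(scores, y)
        from painscale.trial_model import FEATURE_NAMES, ScaleModel

        model = ScaleModel(
            feature_names=FEATURE_NAMES, zscore_means=np.zeros(3), zscore_sds=np.ones(3),
            pc1_loadings=np.array([1.0, 0.0, 0.0]), explained_variance_fraction=1.0,
            sign_oriented=True, gamma=1.0, C=1.0,
            support_vectors=svm["support_vectors"], dual_coef=svm["dual_coef"],
            intercept=svm["intercept"], platt_a=svm["platt_a"], platt_b=svm["platt_b"],
            pain_threshold_pc1=0.0,
        )
        p0 = predict_pain_probability(model, np.array([0.0]))[0]
        assert p0 == pytest.approx(0.5, abs=0.05)
        p_pos = predict_pain_probability(model, np.array([1.0]))[0]
        p_neg = predict_pain_probability(model, np.array([-1.0]))[0]
        assert p_pos > p_neg

    def test_probabilities_bounded_on_wide_grid(self, fitted_model):
        grid = np.linspace(-5, 5, 201)
        p = predict_pain_probability(fitted_model, grid)
        assert np.all((p >= 0) & (p <= 1))

    def test_training_accuracy_on_separated_cohort(self, fitted_model):
        assert fitted_model.provenance["training_accuracy"] >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            train_svm(np.arange(10.0), np.ones(10, dtype=int))

    def test_input_order_invariance(self, rng):
        scores = np.concatenate([rng.normal(-1.5, 0.3, 12), rng.normal(1.5, 0.8, 12)])
        y = np.array([0] * 12 + [1] * 12)
        ids = [f"t{i}" for i in range(24)]
        svm1 = train_svm(scores, y, ids)
        perm = rng.permutation(24)
        svm2 = train_svm(scores[perm], y[perm], [ids[i] for i in perm])
        assert np.array_equal(svm1["support_vectors"], svm2["support_vectors"])
        assert svm1["platt_a"] == svm2["platt_a"]


class TestFitScale:
    def test_group_mean_ordering(self, scored_baseline):
        means = scored_baseline.groupby("stimulus")["pc1_score"].mean()
        assert means["CS"] < means["DB"] < means["LP"] <= means["HP"]

    def test_refit_is_deterministic(self, baseline_cohort, fitted_model):
        trials, _ = baseline_cohort
        again = fit_scale(trials, seed=7)
        assert again.equals(fitted_model)

    def test_missing_stimulus_class_named(self, baseline_cohort):
        trials, _ = baseline_cohort
        with pytest.raises(InputError, match="missing stimulus class HP"):
            fit_scale(trials[trials["stimulus"] != "HP"])

    def test_balanced_orientation_sign_convention(self, scored_baseline):
        means = scored_baseline.groupby("stimulus")["pc1_score"].mean()
        assert means["HP"] > 0 > means["CS"]

    def test_pain_threshold_lies_between_class_means(self, fitted_model, scored_baseline):
        means = scored_baseline.groupby("stimulus")["pc1_score"].mean()
        assert means["CS"] < fitted_model.pain_threshold_pc1 < means["HP"]

    def test_monotone_separation_across_stimulus_intensity(self, fitted_model):
        vfh, _ = generate_cohort(default_config("vfh", seed=21, n_subjects=20))
        base, _ = generate_cohort(default_config("baseline_scale", seed=22, n_subjects=20))
        sb = score_trials(fitted_model, base)
        sv = score_trials(fitted_model, vfh)
        m = sb.groupby("stimulus")["pain_probability"].mean()
        f = sv.groupby("force_grams")["pain_probability"].mean()
        chain = [m["CS"], m["DB"], f[10.0], f[300.0], m["LP"], m["HP"]]
        assert all(a <= b for a, b in zip(chain, chain[1:]))


class TestVonFrey:
    def test_threshold_scan_rule(self):
        series = {1.0: (0, 5), 2.0: (0, 5), 4.0: (1, 5), 6.0: (2, 5), 8.0: (4, 5)}
        assert vfh_threshold(series) == 6.0  # 2/5 = 40% >= 40%

    def test_no_force_qualifies(self):
        assert vfh_threshold({f: (0, 5) for f in (1.0, 2.0, 4.0)}) is None

    def test_first_force_qualifies(self):
        assert vfh_threshold({1.0: (2, 5)}) == 1.0

    def test_unordered_forces_rejected(self):
        with pytest.raises(InputError, match="ascending"):
            vfh_threshold([(2.0, (0, 5)), (1.0, (3, 5))])

    @pytest.mark.parametrize(
        "outcomes,expected", [((1, 1, 0, 0, 0), 40.0), ((0,) * 5, 0.0), ((1,) * 5, 100.0)]
    )
    def test_percent_response_at_10g(self, outcomes, expected):
        assert percent_response_at_10g(outcomes) == expected

    def test_percent_response_requires_five(self):
        with pytest.raises(InputError):
            percent_response_at_10g((1, 0, 1))


class TestFeatureMatrix:
    def test_zero_withdrawal_rows_score_finite(self, scored_baseline):
        z = scored_baseline[["z_composite", "z_speed", "z_height"]].to_numpy()
        assert np.all(np.isfinite(z))
        assert np.all(np.isfinite(scored_baseline["pc1_score"]))

    def test_composite_column_errors_on_missing(self):
        df = pd.DataFrame({"orbital_tightening": [1], "paw_shake": [0]})
        with pytest.raises(Exception, match="jump"):
            composite_scores(df)

    def test_feature_order_is_composite_speed_height(self, baseline_cohort):
        trials, _ = baseline_cohort
        X = feature_matrix(trials.head(5))
        assert np.array_equal(X[:, 1], trials.head(5)["paw_speed_mm_per_s"].to_numpy())
        assert np.array_equal(X[:, 2], trials.head(5)["paw_height_mm"].to_numpy())
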