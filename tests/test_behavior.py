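"""Reverse-correlation kernels, SDT categorization, choice models, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from decidecode.behavior import (
    ChoiceModelFit,
    categorize_sdt,
    contamination_free_boundary,
    exclude_fast_rts,
    fit_choice_logreg,
    fit_confidence_logreg,
    kernel_slope,
    psychophysical_kernel,
    roc_auc,
)
from decidecode.group_stats import fdr_correct
from decidecode.observer import ObserverParams
from decidecode.trials import SAMPLE_COLUMNS, generate_trial_table


def brute_force_auc(scores, labels):
    """Exhaustive pair counting with ties scored 0.5."""
    pos = np.asarray(scores)[np.asarray(labels, bool)]
    neg = np.asarray(scores)[~np.asarray(labels, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_tied_toy_set_matches_pair_counting(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0])
        labels = np.array([0, 0, 1, 0, 1, 1, 0, 1], bool)
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-15)

    def test_chance_level_with_independent_labels(self, rng):
        scores = rng.normal(size=10000)
        labels = rng.random(10000) < 0.5
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200).round(1)  # force ties
        labels = rng.random(200) < 0.4
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_sign_flip_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=30).round(1)
        labels = np.zeros(30, bool)
        labels[:r.integers(1, 29)] = True
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(
            1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


def test_categorize_sdt_toy_table():
    t = pd.DataFrame({
        "stimulus_category": ["stronger", "stronger", "weaker", "weaker"],
        "choice": ["stronger", "weaker", "stronger", "weaker"],
    })
    assert list(categorize_sdt(t)) == ["hit", "miss", "false_alarm", "correct_reject"]


def test_categorize_sdt_drops_missing_choice():
    t = pd.DataFrame({
        "stimulus_category": ["stronger", "weaker"],
        "choice": ["stronger", None],
    })
    out = categorize_sdt(t)
    assert len(out) == 1 and out.attrs["n_excluded_missing_choice"] == 1


class TestPsychophysicalKernel:
    def test_matches_brute_force_roc_integration(self, rng):
        """Equals an explicit ROC-curve + trapezoid oracle on a 200-trial fixture."""
        t = generate_trial_table(n_subjects=1, n_trials=200, seed=2)

        def roc_trapezoid(v, labels):
            thresholds = np.unique(v)[::-1]
            tpr = [0.0]
            fpr = [0.0]
            pos, neg = labels.sum(), (~labels).sum()
            for th in thresholds:
                tpr.append((v[labels] >= th).sum() / pos)
                fpr.append((v[~labels] >= th).sum() / neg)
            return np.trapezoid(tpr, fpr)

        expected = np.empty(10)
        cat = (t["stimulus_category"] == "stronger").to_numpy()
        cho = (t["choice"] == "stronger").to_numpy()
        for i, col in enumerate(SAMPLE_COLUMNS):
            v = t[col].to_numpy()
            expected[i] = 0.5 * (roc_trapezoid(v[cat], cho[cat])
                                 + roc_trapezoid(v[~cat], cho[~cat]))
        np.testing.assert_allclose(psychophysical_kernel(t), expected, atol=1e-12)

    def test_null_kernel_at_chance(self, coin_trials):
        k = psychophysical_kernel(coin_trials)
        np.testing.assert_allclose(k, 0.5, atol=0.05)

    def test_first_sample_only_observer(self, rng):
        """An observer weighting only sample 1 yields AUC > 0.9 there, ~0.5 elsewhere."""
        w = np.zeros(10)
        w[0] = 1.0
        obs = ObserverParams(weights=w, internal_noise_sd=0.01)
        # non-zero offset keeps the category conditioning from inducing
        # spurious negative correlations at the unused positions
        t = generate_trial_table(n_subjects=1, n_trials=4000, seed=4,
                                 adaptive=False, fixed_offset=0.05, observer=obs)
        k = psychophysical_kernel(t)
        assert k[0] > 0.9
        np.testing.assert_allclose(k[1:], 0.5, atol=0.04)

    def test_invariant_under_monotone_transform(self, observer_trials):
        base = psychophysical_kernel(observer_trials)
        t = observer_trials.copy()
        for col in SAMPLE_COLUMNS:
            t[col] = np.exp(3.0 * t[col])  # strictly increasing
        np.testing.assert_allclose(psychophysical_kernel(t), base, atol=1e-12)

    def test_empty_cell_propagates_missing(self):
        t = pd.DataFrame({
            "stimulus_category": ["stronger"] * 4,
            "choice": ["stronger", "stronger", "weaker", "weaker"],
            **{c: np.random.default_rng(0).random(4) for c in SAMPLE_COLUMNS},
        })
        k = psychophysical_kernel(t)  # weaker-category cell entirely absent
        assert np.isfinite(k).all()   # the hit/miss cell still defines the value
        t_onecell = t.assign(choice=["stronger"] * 4)
        assert np.isnan(psychophysical_kernel(t_onecell)).all()


def test_kernel_slope_exact_and_constant():
    assert kernel_slope(np.full(10, 0.6)) == pytest.approx(0.0, abs=1e-12)
    series = 0.6 - 0.01 * np.arange(10)
    assert kernel_slope(series) == pytest.approx(-0.01, abs=1e-12)
    with pytest.raises(ValueError):
        kernel_slope(np.full(10, np.nan))


def test_fdr_false_positive_rate_under_null_generator():
    """BH across 10 positions rejects in <= ~5% of null datasets."""
    rng = np.random.default_rng(0)
    from scipy.stats import ttest_1samp

    n_datasets, n_subjects = 300, 15
    any_reject = 0
    for _ in range(n_datasets):
        # per-subject kernels under the null are AUCs of independent scores:
        # simulate directly from the AUC sampling distribution machinery
        kernels = np.empty((n_subjects, 10))
        for s in range(n_subjects):
            cho = rng.random(160) < 0.5
            cat = rng.random(160) < 0.5
            if cho[cat].all() or (~cho[cat]).all() or cho[~cat].all() or (~cho[~cat]).all():
                cho[:2] = [True, False]
            scores = rng.normal(size=(160, 10))
            for i in range(10):
                a1 = roc_auc(scores[cat, i], cho[cat])
                a2 = roc_auc(scores[~cat, i], cho[~cat])
                kernels[s, i] = 0.5 * (a1 + a2)
        p = ttest_1samp(kernels, 0.5, axis=0).pvalue
        any_reject += fdr_correct(p).any()
    rate = any_reject / n_datasets
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_datasets)


def test_kernel_recovers_generating_weights():
    """Rank correlation between weights and kernel deviations >= 0.9."""
    from scipy.stats import spearmanr

    w = np.exp(-0.25 * np.arange(10))
    obs = ObserverParams(weights=w, internal_noise_sd=0.1)
    devs = []
    for s in range(15):
        t = generate_trial_table(n_subjects=1, n_trials=2000, seed=100 + s,
                                 adaptive=False, fixed_offset=0.01, observer=obs)
        devs.append(psychophysical_kernel(t) - 0.5)
    rho = spearmanr(w, np.mean(devs, axis=0)).statistic
    assert rho >= 0.9


class TestChoiceLogreg:
    def test_recovers_generating_coefficients(self, rng):
        beta = 8.0 * np.exp(-0.15 * np.arange(10))
        beta0 = -beta.sum() * 0.5
        X = rng.normal(0.5, 0.1, size=(20000, 10))
        y = rng.random(20000) < expit(X @ beta + beta0)
        t = pd.DataFrame(X, columns=SAMPLE_COLUMNS)
        t["choice"] = np.where(y, "stronger", "weaker")
        fit = fit_choice_logreg(t)
        rel_err = np.abs(fit.coefficients[1:] / beta - 1.0)
        assert rel_err.mean() <= 0.05       # unbiased recovery on average
        assert rel_err.max() <= 0.12        # per-coefficient sampling noise
        assert isinstance(fit, ChoiceModelFit)

    def test_noiseless_observer_perfectly_predicted(self):
        obs = ObserverParams(weights=np.ones(10), internal_noise_sd=1e-10)
        t = generate_trial_table(n_subjects=1, n_trials=2000, seed=6,
                                 adaptive=False, fixed_offset=0.0, observer=obs)
        assert fit_choice_logreg(t).cv_accuracy > 0.98

    def test_constant_contrasts_give_majority_rate(self, rng):
        t = pd.DataFrame(np.full((300, 10), 0.5), columns=SAMPLE_COLUMNS)
        t["choice"] = np.where(rng.random(300) < 0.7, "stronger", "weaker")
        fit = fit_choice_logreg(t)
        majority = max((t["choice"] == "stronger").mean(),
                       (t["choice"] == "weaker").mean())
        assert fit.cv_accuracy == pytest.approx(majority, abs=0.05)

    def test_stratified_folds_preserve_class_proportions(self, observer_trials):
        fit = fit_choice_logreg(observer_trials)
        y = (observer_trials["choice"] == "stronger").to_numpy()
        overall = y.mean()
        for k in range(5):
            in_fold = fit.fold_assignments == k
            n_pos_expected = overall * in_fold.sum()
            assert abs(y[in_fold].sum() - n_pos_expected) <= 1 + 1e-9


def test_confidence_model_beats_chance_for_dv_based_confidence(observer_trials):
    fits = fit_confidence_logreg(observer_trials)
    for ch in ("stronger", "weaker"):
        assert fits[ch].cv_accuracy > 0.5


def test_confidence_model_at_chance_for_coin_confidence(rng):
    t = generate_trial_table(n_subjects=1, n_trials=1000, seed=8, adaptive=False)
    t["confidence"] = np.where(rng.random(len(t)) < 0.5, "high", "low")
    fits = fit_confidence_logreg(t)
    for ch in ("stronger", "weaker"):
        assert fits[ch].cv_accuracy == pytest.approx(0.5, abs=0.07)


def test_exclude_fast_rts_boundary_kept():
    t = pd.DataFrame({"rt": [1.0, 1.225, 1.3]})
    out = exclude_fast_rts(t)
    assert len(out) == 2 and out["rt"].min() == 1.225
    all_slow = pd.DataFrame({"rt": [1.3, 2.0]})
    assert exclude_fast_rts(all_slow).equals(all_slow)


def test_contamination_free_boundary_arithmetic():
    assert contamination_free_boundary() == pytest.approx(1.1, abs=1e-12)
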