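"""Nested CV training, AUC, bootstrap summaries, z-scoring, cross-prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import painpipe as pp

from conftest import small_generator_config


# ---------------------------------------------------------------------------
# auc
# ---------------------------------------------------------------------------

def _auc_bruteforce(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("scores,labels", [
    ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]),
    ([1, 2, 3, 4], [1, 1, 0, 0]),
    ([0.2, 0.2, 0.2, 0.2], [0, 1, 0, 1]),  # all ties -> 0.5
    ([0, 1, 2, 3, 4, 5], [0, 0, 0, 1, 1, 1]),
])
def test_auc_matches_pairwise_concordance(scores, labels):
    assert pp.auc(scores, labels) == pytest.approx(
        _auc_bruteforce(scores, labels), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=4, max_size=30),
       st.data())
def test_auc_property_matches_bruteforce(scores, data):
    labels = data.draw(st.lists(st.integers(0, 1), min_size=len(scores),
                                max_size=len(scores)))
    if len(set(labels)) < 2:
        labels[0], labels[1] = 0, 1
    assert pp.auc(scores, labels) == pytest.approx(
        _auc_bruteforce(scores, labels), abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(pp.DataError):
        pp.auc([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# bootstrap summary
# ---------------------------------------------------------------------------

def test_bootstrap_constant_list_gives_degenerate_ci():
    s = pp.bootstrap_summary([0.7] * 10, n_bootstrap=100, seed=1)
    assert s.ci_lower == s.ci_upper == s.mean == 0.7


def test_bootstrap_matches_independent_resampler(rng):
    values = rng.random(25)
    s = pp.bootstrap_summary(values, n_bootstrap=500, seed=42)
    # independent re-implementation of the same seeded scheme
    rng2 = np.random.default_rng(42)
    idx = rng2.integers(0, 25, size=(500, 25))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    assert s.ci_lower == pytest.approx(lo, abs=1e-12)
    assert s.ci_upper == pytest.approx(hi, abs=1e-12)
    assert s.ci_lower <= s.mean <= s.ci_upper


def test_bootstrap_ci_converges_with_more_resamples(rng):
    values = rng.normal(0.7, 0.05, 25)
    a = pp.bootstrap_summary(values, n_bootstrap=1000, seed=0)
    b = pp.bootstrap_summary(values, n_bootstrap=100000, seed=1)
    half_sd = values.std(ddof=1) / 2
    assert abs(a.ci_lower - b.ci_lower) < half_sd
    assert abs(a.ci_upper - b.ci_upper) < half_sd


# ---------------------------------------------------------------------------
# AUC z-scoring
# ---------------------------------------------------------------------------

def test_zscore_row_matches_hand_computation():
    m = pd.DataFrame([[0.6, 0.7, 0.8]], index=["dx"], columns=list("abc"))
    z, mask = pp.zscore_auc_matrix(m)
    sd = np.std([0.6, 0.7, 0.8], ddof=1)
    np.testing.assert_allclose(z.iloc[0], np.array([-0.1, 0.0, 0.1]) / sd,
                               atol=1e-12)
    # below-mean entries suppressed, above-mean kept (exact-zero is fp-ambiguous)
    assert mask.iloc[0, 0] and not mask.iloc[0, 2]


def test_zscore_identical_entries_rejected():
    m = pd.DataFrame([[0.7, 0.7, 0.7]], index=["dx"], columns=list("abc"))
    with pytest.raises(pp.DataError):
        pp.zscore_auc_matrix(m)


def test_zscore_duplicated_rows_same_zscores():
    m = pd.DataFrame([[0.6, 0.75, 0.9]] * 3, index=list("xyz"), columns=list("abc"))
    z, _ = pp.zscore_auc_matrix(m)
    assert (z.nunique(axis=0) == 1).all()


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

def test_balanced_class_weights_formula():
    """sklearn 'balanced' weights equal n/(2 n_c): verified on 100 subjects
    with 10 cases."""
    from sklearn.utils.class_weight import compute_class_weight
    y = np.array([1] * 10 + [0] * 90)
    w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
    assert w[1] == pytest.approx(100 / (2 * 10))
    assert w[0] == pytest.approx(100 / (2 * 90))


def test_partition_integrity_and_auc_list_shape(small_bundle, small_cohort):
    cfg = small_bundle.config
    n = small_cohort.n_subjects
    assert len(small_bundle.auc_list) == cfg.repeats * cfg.outer_folds
    for r in range(cfg.repeats):
        folds = [f for f in small_bundle.folds if f.repeat == r]
        seen = np.concatenate([f.val_idx for f in folds])
        assert len(seen) == n and len(set(seen)) == n
    for f in small_bundle.folds:
        assert ((f.val_probs > 0) & (f.val_probs < 1)).all()


def test_bundle_bit_reproducible(small_cohort, fast_cv):
    a = pp.nested_cv_train(small_cohort.X["blood"], small_cohort.y["dx0"].to_numpy(),
                           small_cohort.C, fast_cv)
    b = pp.nested_cv_train(small_cohort.X["blood"], small_cohort.y["dx0"].to_numpy(),
                           small_cohort.C, fast_cv)
    for fa, fb in zip(a.folds, b.folds):
        assert np.array_equal(fa.coef, fb.coef)
        assert fa.lam == fb.lam and fa.intercept == fb.intercept
        assert np.array_equal(fa.val_scores, fb.val_scores)


def test_validation_auc_tracks_bayes_oracle(fast_cv):
    """With a strong planted signal the nested-CV AUC approaches the AUC of
    the true linear predictor (the Bayes-optimal score)."""
    cfg = small_generator_config(seed=21, n=4000, leakage=0.0, psy_weight=0.0,
                                 effect_scale=2.0)
    coh = pp.generate_cohort(cfg)
    oracle = pp.auc(coh.truth["eta"]["dx0"], coh.y["dx0"].to_numpy())
    b = pp.nested_cv_train(coh.X["blood"], coh.y["dx0"].to_numpy(), coh.C, fast_cv)
    assert abs(np.mean(b.auc_list) - oracle) < 0.03


def test_permuted_labels_give_chance_auc(small_cohort, fast_cv):
    rng = np.random.default_rng(5)
    y = rng.permutation(small_cohort.y["dx0"].to_numpy())
    b = pp.nested_cv_train(small_cohort.X["blood"], y, small_cohort.C, fast_cv)
    vals = np.asarray(b.auc_list)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 0.5) <= 3 * max(se, 0.01)


def test_single_class_and_tiny_minority_rejected(small_cohort, fast_cv):
    with pytest.raises(pp.DataError):
        pp.nested_cv_train(small_cohort.X["blood"],
                           np.zeros(small_cohort.n_subjects),
                           small_cohort.C, fast_cv)
    y = np.zeros(small_cohort.n_subjects)
    y[:2] = 1  # fewer cases than outer folds
    with pytest.raises(pp.DataError):
        pp.nested_cv_train(small_cohort.X["blood"], y, small_cohort.C, fast_cv)


# ---------------------------------------------------------------------------
# cross-prediction
# ---------------------------------------------------------------------------

def test_cross_predict_self_consistent(small_bundle, small_cohort):
    """Reapplying each fold model to its own validation rows reproduces the
    stored out-of-fold scores and AUCs."""
    X, C = small_cohort.X["blood"], small_cohort.C
    y = small_cohort.y["dx0"].to_numpy()
    for f in small_bundle.folds:
        Xt = pp.apply_residualizer(f.residualizer, X.iloc[f.val_idx],
                                   C.iloc[f.val_idx]).to_numpy()
        s = Xt @ f.coef + f.intercept
        np.testing.assert_allclose(s, f.val_scores, atol=1e-10)
        assert pp.auc(s, y[f.val_idx]) == pytest.approx(f.auc, abs=1e-12)


def test_cross_predict_shared_mechanism_transfers(fast_cv):
    """A model trained on one diagnosis discriminates another diagnosis
    generated from the same planted coefficients."""
    cfg = small_generator_config(seed=31, n=3000, n_diagnoses=2,
                                 shared_beta=True, psy_weight=0.0)
    coh = pp.generate_cohort(cfg)
    b = pp.nested_cv_train(coh.X["blood"], coh.y["dx0"].to_numpy(), coh.C, fast_cv)
    self_auc = np.mean(b.auc_list)
    res = pp.cross_predict(b, coh.X["blood"], coh.y["dx1"].to_numpy(), coh.C)
    assert abs(res["auc"] - self_auc) < 0.05
    assert 0 <= res["sensitivity"] <= 1 and 0 <= res["specificity"] <= 1


def test_cross_predict_independent_labels_chance(small_bundle, small_cohort, rng):
    y = rng.integers(0, 2, small_cohort.n_subjects)
    res = pp.cross_predict(small_bundle, small_cohort.X["blood"], y, small_cohort.C)
    assert abs(res["auc"] - 0.5) < 0.05


def test_cross_predict_feature_mismatch_rejected(small_bundle, small_cohort):
    X2 = small_cohort.X["blood"].rename(columns=lambda c: c + "_renamed")
    with pytest.raises(pp.DataError):
        pp.cross_predict(small_bundle, X2, small_cohort.y["dx0"].to_numpy(),
                         small_cohort.C)
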