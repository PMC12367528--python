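"""Encoding maps, composite signatures, thresholding, permutation tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import painpipe as pp
from painpipe.encoding import _pearson_columns


def _toy_signature(coefs, names=None):
    coefs = np.asarray(coefs, float)
    names = names or [f"f{i}" for i in range(len(coefs))]
    return pp.CompositeSignature(feature_names=list(names), coefficients=coefs,
                                 contributing_models=["toy"])


# ---------------------------------------------------------------------------
# structure coefficients
# ---------------------------------------------------------------------------

def test_pearson_columns_hand_oracle(rng):
    """3-feature toy: coefficients equal direct per-column correlation with
    the decision score X @ beta."""
    X = rng.standard_normal((200, 3))
    beta = np.array([1.0, -2.0, 0.5])
    s = X @ beta
    r, zero = _pearson_columns(X, s)
    for j in range(3):
        assert r[j] == pytest.approx(np.corrcoef(X[:, j], s)[0, 1], abs=1e-12)
    assert not zero.any()


def test_single_feature_model_gives_signed_unity(rng):
    X = rng.standard_normal((100, 1))
    r, _ = _pearson_columns(X, X[:, 0] * -3.0 + 1.0)
    assert r[0] == pytest.approx(-1.0, abs=1e-12)


def test_orthogonal_feature_near_zero_and_zero_variance_flagged(rng):
    x = rng.standard_normal(500)
    s = rng.standard_normal(500)
    s -= (s @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
    X = np.column_stack([x, np.full(500, 2.0)])
    r, zero = _pearson_columns(X, s)
    assert abs(r[0]) < 1e-10
    assert zero[1] and r[1] == 0.0


def test_anticorrelated_features_get_opposite_coefficients(rng):
    x = rng.standard_normal(300)
    X = np.column_stack([x, -x, rng.standard_normal(300)])
    s = X @ np.array([1.0, 0.0, 0.3])
    r, _ = _pearson_columns(X, s)
    assert r[0] == pytest.approx(-r[1], abs=1e-12)


def test_structure_coefficients_from_bundle(small_bundle, small_cohort):
    m = pp.structure_coefficients(small_bundle, small_cohort.X["blood"],
                                  small_cohort.C)
    assert len(m.coefficients) == 20
    assert np.all(np.abs(m.coefficients) <= 1.0)
    # positive planted coefficients appear elevated in cases on average
    beta = small_cohort.truth["beta"][("blood", "dx0")]
    strong = np.abs(beta) > np.abs(beta).max() * 0.5
    assert np.corrcoef(m.coefficients[strong], beta[strong])[0, 1] > 0.8


# ---------------------------------------------------------------------------
# composite signature
# ---------------------------------------------------------------------------

def test_composite_identical_maps_equals_input(rng):
    c = rng.standard_normal(10)
    maps = [pp.EncodingMap([f"f{i}" for i in range(10)], c.copy(), f"m{k}")
            for k in range(3)]
    sig = pp.composite_signature(maps)
    np.testing.assert_allclose(sig.coefficients, c)
    np.testing.assert_allclose(sig.coefficient_sd, 0.0, atol=1e-12)


def test_composite_of_exact_negatives_is_zero(rng):
    c = rng.standard_normal(8)
    names = [f"f{i}" for i in range(8)]
    sig = pp.composite_signature([pp.EncodingMap(names, c, "a"),
                                  pp.EncodingMap(names, -c, "b")])
    np.testing.assert_allclose(sig.coefficients, 0.0, atol=1e-15)


def test_composite_matches_loop_oracle(rng):
    names = [f"f{i}" for i in range(52)]
    maps = [pp.EncodingMap(names, rng.standard_normal(52), f"m{k}")
            for k in range(13)]
    sig = pp.composite_signature(maps)
    for j in range(52):
        oracle = sum(m.coefficients[j] for m in maps) / 13
        assert sig.coefficients[j] == pytest.approx(oracle, abs=1e-12)


def test_composite_feature_mismatch_rejected(rng):
    a = pp.EncodingMap(["x", "y"], rng.standard_normal(2), "a")
    b = pp.EncodingMap(["y", "x"], rng.standard_normal(2), "b")
    with pytest.raises(pp.DataError):
        pp.composite_signature([a, b])


# ---------------------------------------------------------------------------
# simplify / threshold
# ---------------------------------------------------------------------------

def test_simplify_matches_sort_oracle(rng):
    c = rng.standard_normal(52)
    sig = _toy_signature(c)
    out = pp.simplify_signature(sig, 10)
    kept = set(np.flatnonzero(out.coefficients))
    oracle = set(np.argsort(-np.abs(c), kind="stable")[:10])
    assert kept == oracle
    np.testing.assert_array_equal(out.coefficients[list(kept)], c[list(kept)])


def test_simplify_exactly_k_nonzeros_unchanged():
    c = np.array([0.0, 1.0, 0.0, -2.0, 3.0])
    out = pp.simplify_signature(_toy_signature(c), 3)
    np.testing.assert_array_equal(out.coefficients, c)


def test_simplify_tie_keeps_earlier_feature():
    c = np.array([0.5, -0.5, 0.5, 0.1])
    out = pp.simplify_signature(_toy_signature(c), 2)
    assert np.flatnonzero(out.coefficients).tolist() == [0, 1]


def test_threshold_ceiling_rule_and_identity(rng):
    c = rng.standard_normal(52)
    sig = _toy_signature(c)
    out = pp.threshold_signature(sig, 0.10)
    assert (out.coefficients != 0).sum() == 6  # ceil(5.2)
    full = pp.threshold_signature(sig, 1.0)
    np.testing.assert_array_equal(full.coefficients, c)


def test_threshold_ladder_is_nested(rng):
    c = rng.standard_normal(80)
    sig = _toy_signature(c)
    prev = None
    for dens in (1.0, 0.5, 0.25, 0.10, 0.05, 0.01, 0.005):
        kept = set(np.flatnonzero(pp.threshold_signature(sig, dens).coefficients))
        if prev is not None:
            assert kept <= prev
        prev = kept


def test_threshold_invalid_density_rejected():
    sig = _toy_signature([1.0, 2.0])
    for bad in (0.0, -0.5, 1.5):
        with pytest.raises(pp.ConfigError):
            pp.threshold_signature(sig, bad)


# ---------------------------------------------------------------------------
# subject scoring
# ---------------------------------------------------------------------------

def test_score_subjects_matches_matrix_oracle(small_cohort, rng):
    res = pp.fit_residualizer(small_cohort.X["blood"], small_cohort.C)
    sig = _toy_signature(rng.standard_normal(20),
                         names=list(small_cohort.X["blood"].columns))
    scores = pp.score_subjects(sig, small_cohort.X["blood"], small_cohort.C, res)
    Xt = pp.apply_residualizer(res, small_cohort.X["blood"], small_cohort.C)
    np.testing.assert_allclose(scores, Xt.to_numpy() @ sig.coefficients, atol=1e-10)
    # all-zero signature
    zero = _toy_signature(np.zeros(20), names=list(small_cohort.X["blood"].columns))
    assert (pp.score_subjects(zero, small_cohort.X["blood"], small_cohort.C, res) == 0).all()
    # one-hot signature equals that standardized column
    onehot = np.zeros(20); onehot[3] = 1.0
    oh = _toy_signature(onehot, names=list(small_cohort.X["blood"].columns))
    np.testing.assert_allclose(
        pp.score_subjects(oh, small_cohort.X["blood"], small_cohort.C, res),
        Xt.iloc[:, 3].to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# similarity and permutation null
# ---------------------------------------------------------------------------

def test_similarity_self_and_negative(rng):
    c = rng.standard_normal(20)
    sim = pp.encoding_similarity(c, c, n_permutations=99, seed=0)
    assert sim["r"] == pytest.approx(1.0)
    assert sim["p"] == pytest.approx(1 / 100)
    assert pp.encoding_similarity(c, -c, n_permutations=99, seed=0)["r"] == pytest.approx(-1.0)


def test_similarity_p_matches_exhaustive_enumeration(rng):
    """6-feature instance: the permutation p equals the exact proportion over
    all 720 feature permutations (up to the +1 smoothing)."""
    a = np.array([0.9, -0.2, 0.4, 0.1, -0.7, 0.3])
    b = np.array([1.1, -0.1, 0.2, 0.0, -0.9, 0.5])
    r_obs = np.corrcoef(a, b)[0, 1]
    ac, bc = a - a.mean(), b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    exact = np.mean([abs(ac[list(p)] @ bc / denom) >= abs(r_obs) - 1e-15
                     for p in itertools.permutations(range(6))])
    sim = pp.encoding_similarity(a, b, n_permutations=5000, seed=3)
    assert sim["r"] == pytest.approx(r_obs, abs=1e-12)
    assert sim["p"] == pytest.approx(exact, abs=0.01)


def test_similarity_zero_variance_rejected():
    with pytest.raises(pp.DataError):
        pp.encoding_similarity(np.ones(5), np.arange(5.0))


def test_permutation_null_auc_behaviour(small_cohort, rng):
    res = pp.fit_residualizer(small_cohort.X["blood"], small_cohort.C)
    y = small_cohort.y["dx0"].to_numpy()
    # label-independent signature: observed inside the null
    noise_sig = _toy_signature(rng.standard_normal(20),
                               names=list(small_cohort.X["blood"].columns))
    out = pp.permutation_null_auc(noise_sig, small_cohort.X["blood"], y,
                                  small_cohort.C, res, n_permutations=300, seed=1)
    se = out["null_sd"] / np.sqrt(300)
    assert abs(out["null_mean"] - 0.5) <= 3 * se
    assert abs(out["z"]) < 3
    # planted-signal signature: strongly significant
    beta = small_cohort.truth["beta"][("blood", "dx0")]
    true_sig = _toy_signature(beta, names=list(small_cohort.X["blood"].columns))
    out2 = pp.permutation_null_auc(true_sig, small_cohort.X["blood"], y,
                                   small_cohort.C, res, n_permutations=300, seed=2)
    assert out2["p"] <= 0.01
    assert out2["observed_auc"] > 0.6
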