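"""Band features, min-max scaling, LDA, votes, and span selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stnmer import (BandFeatures, DepthFrequencyMap, classify_depths,
                    minmax_normalize, select_track, train_lda)
from stnmer.classify import extract_band_features, load_default_model


def _dfm(values, freqs=None, depths=None):
    values = np.asarray(values, dtype=float)
    n_d, n_f = values.shape
    freqs = np.arange(n_f, dtype=float) if freqs is None else freqs
    depths = 5.0 - np.arange(n_d, dtype=float) if depths is None else depths
    return DepthFrequencyMap("center", depths, freqs, values,
                             scale="log_normalized_db")


def _features(beta_by_track, hfo_by_track, depths=None, normalized=False):
    tracks = tuple(beta_by_track)
    n = len(next(iter(beta_by_track.values())))
    depths = 2.0 - 0.5 * np.arange(n) if depths is None else depths
    return BandFeatures(tracks, np.asarray(depths, float),
                        {t: np.asarray(v, float) for t, v in beta_by_track.items()},
                        {t: np.asarray(v, float) for t, v in hfo_by_track.items()},
                        normalized=normalized)


# ---------------------------------------------------------------------------
# extract_band_features
# ---------------------------------------------------------------------------

def test_features_of_flat_and_banded_maps():
    freqs = np.arange(0.0, 500.0)
    zero = _dfm(np.zeros((3, 500)), freqs=freqs)
    b, h = extract_band_features(zero)
    np.testing.assert_array_equal(b, 0.0)
    np.testing.assert_array_equal(h, 0.0)

    vals = np.zeros((2, 500))
    vals[:, (freqs >= 11) & (freqs <= 32)] = 10.0
    banded = _dfm(vals, freqs=freqs)
    b, h = extract_band_features(banded)
    np.testing.assert_allclose(b, 10.0)
    np.testing.assert_allclose(h, 0.0)


def test_features_match_bin_loop_oracle():
    rng = np.random.default_rng(0)
    freqs = np.arange(0.0, 500.0, 0.5)
    vals = rng.standard_normal((7, len(freqs)))
    m = _dfm(vals, freqs=freqs)
    beta, hfo = extract_band_features(m)
    for band, got in (((11.0, 32.0), beta), ((200.0, 400.0), hfo)):
        for di in range(7):
            acc, cnt = 0.0, 0
            for fi, f in enumerate(freqs):
                if band[0] <= f <= band[1]:
                    acc += vals[di, fi]
                    cnt += 1
            assert abs(got[di] - acc / cnt) < 1e-12


def test_features_require_normalized_scale_and_valid_band():
    lin = _dfm(np.ones((2, 500)))
    lin.scale = "linear"
    with pytest.raises(ValueError):
        extract_band_features(lin)
    small = _dfm(np.ones((2, 5)), freqs=np.arange(5.0))
    with pytest.raises(ValueError):
        extract_band_features(small, hfo_band=(200.0, 400.0))


# ---------------------------------------------------------------------------
# minmax_normalize
# ---------------------------------------------------------------------------

def test_minmax_basic_and_degenerate():
    f = _features({"center": [2.0, 4.0, 6.0]}, {"center": [1.0, 1.0, 1.0]})
    with pytest.warns(UserWarning, match="constant"):
        out = minmax_normalize(f)
    np.testing.assert_allclose(out.beta["center"], [0.0, 0.5, 1.0])
    np.testing.assert_allclose(out.hfo["center"], 0.5)
    assert out.normalized


def test_minmax_pools_across_tracks():
    f = _features({"center": [0.0, 10.0], "anterior": [5.0, 20.0]},
                  {"center": [1.0, 2.0], "anterior": [0.0, 4.0]})
    out = minmax_normalize(f)
    np.testing.assert_allclose(out.beta["center"], [0.0, 0.5])
    np.testing.assert_allclose(out.beta["anterior"], [0.25, 1.0])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
def test_minmax_affine_invariance(a, b):
    beta = np.array([1.0, 3.0, -2.0, 7.0])
    hfo = np.array([0.0, 2.0, 5.0, 1.0])
    base = minmax_normalize(_features({"center": beta}, {"center": hfo}))
    scaled = minmax_normalize(_features({"center": a * beta + b},
                                        {"center": a * hfo + b}))
    np.testing.assert_allclose(base.beta["center"], scaled.beta["center"],
                               atol=1e-9)
    np.testing.assert_allclose(base.hfo["center"], scaled.hfo["center"],
                               atol=1e-9)


# ---------------------------------------------------------------------------
# train_lda
# ---------------------------------------------------------------------------

def _gaussian_classes(rng, mu, n=500):
    x_out = rng.standard_normal((n, 2))
    x_in = rng.standard_normal((n, 2)) + np.asarray(mu)
    X = np.vstack([x_out, x_in])
    y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
    return X, y


def test_lda_direction_matches_analytic():
    X, y = _gaussian_classes(np.random.default_rng(0), (2.0, 2.0))
    model = train_lda(X, y)
    w = np.asarray(model.weights)
    w = w / np.linalg.norm(w)
    np.testing.assert_allclose(w, np.sqrt(0.5), atol=0.1)


def test_lda_label_swap_negates():
    X, y = _gaussian_classes(np.random.default_rng(1), (1.0, 2.0), n=200)
    m1 = train_lda(X, y)
    m2 = train_lda(X, ~y)
    np.testing.assert_allclose(m1.weights, -np.asarray(m2.weights), atol=1e-9)
    assert abs(m1.bias + m2.bias) < 1e-9


def test_lda_separable_resubstitution_accuracy():
    X, y = _gaussian_classes(np.random.default_rng(2), (6.0, 6.0), n=300)
    model = train_lda(X, y)
    pred = model.decision_distance(X) > 0
    assert np.all(pred == y)


def test_lda_requires_both_classes():
    X = np.random.default_rng(3).standard_normal((10, 2))
    with pytest.raises(ValueError):
        train_lda(X, np.ones(10, bool))


# ---------------------------------------------------------------------------
# classify_depths / select_track
# ---------------------------------------------------------------------------

def test_boundary_feature_votes_out():
    model = train_lda(*_gaussian_classes(np.random.default_rng(4), (2.0, 2.0)))
    w = np.asarray(model.weights)
    x_boundary = -model.bias * w / (w @ w)  # distance exactly 0
    f = _features({"center": [x_boundary[0]]}, {"center": [x_boundary[1]]},
                  normalized=True)
    dec = classify_depths(model, f)
    assert abs(dec.decision_distances["center"][0]) < 1e-9
    assert not dec.votes["center"][0]


def test_distances_affine_in_weights_and_votes_match_sign_oracle():
    from stnmer.classify import LdaModel
    rng = np.random.default_rng(5)
    beta = {t: rng.uniform(0, 1, 6) for t in ("center", "anterior")}
    hfo = {t: rng.uniform(0, 1, 6) for t in ("center", "anterior")}
    f = _features(beta, hfo, normalized=True)
    m1 = LdaModel(weights=(1.0, 2.0), bias=-1.0)
    m2 = LdaModel(weights=(2.0, 4.0), bias=-2.0)
    d1 = classify_depths(m1, f)
    d2 = classify_depths(m2, f)
    for t in f.track_labels:
        np.testing.assert_allclose(2 * d1.decision_distances[t],
                                   d2.decision_distances[t], atol=1e-12)
        np.testing.assert_array_equal(d1.votes[t], d2.votes[t])
        brute = np.array([beta[t][i] * 1.0 + hfo[t][i] * 2.0 - 1.0 > 0
                          for i in range(6)])
        np.testing.assert_array_equal(d1.votes[t], brute)


def test_unnormalized_features_rejected():
    model = load_default_model()
    f = _features({"center": [3.0]}, {"center": [4.0]}, normalized=False)
    with pytest.raises(ValueError, match="normalized"):
        classify_depths(model, f)


def _decision(votes_by_track, distances=None, step=0.5):
    from stnmer.classify import TrackDecision
    tracks = tuple(votes_by_track)
    n = len(next(iter(votes_by_track.values())))
    depths = 2.0 - step * np.arange(n)
    votes = {t: np.asarray(v, bool) for t, v in votes_by_track.items()}
    if distances is None:
        distances = {t: np.where(votes[t], 1.0, -1.0) for t in tracks}
    return TrackDecision(tracks, depths, distances, votes)


def test_longest_span_selection_example():
    dec = select_track(_decision({
        "center": [0, 1, 1, 1, 0],
        "anterior": [0, 1, 0, 1, 0],
    }))
    assert dec.selected_track == "center"
    best = max(dec.spans["center"], key=lambda s: s.length_mm)
    assert best.length_mm == pytest.approx(1.5)
    assert max(s.length_mm for s in dec.spans["anterior"]) == pytest.approx(0.5)
    assert dec.estimated_entry_mm == pytest.approx(1.5)


def test_all_out_returns_none():
    dec = select_track(_decision({"center": [0, 0, 0], "anterior": [0, 0, 0]}))
    assert dec.selected_track is None
    assert dec.estimated_entry_mm is None
    assert all(len(s) == 0 for s in dec.spans.values())


def test_tie_breaks_by_mean_distance_then_label_order():
    d = {"center": np.array([-1.0, 2.0, 2.0, -1.0]),
         "anterior": np.array([-1.0, 5.0, 5.0, -1.0])}
    v = {t: x > 0 for t, x in d.items()}
    dec = select_track(_decision({t: v[t] for t in d}, distances=d))
    assert dec.selected_track == "anterior"  # same span, larger distance

    d2 = {"anterior": np.array([-1.0, 2.0, 2.0, -1.0]),
          "center": np.array([-1.0, 2.0, 2.0, -1.0])}
    v2 = {t: x > 0 for t, x in d2.items()}
    dec2 = select_track(_decision({t: v2[t] for t in d2}, distances=d2))
    assert dec2.selected_track == "center"  # full tie: canonical order


def test_count_criterion_differs_from_span():
    votes = {"center": [1, 1, 1, 0, 0, 0, 0],
             "anterior": [1, 1, 0, 1, 1, 0, 1]}
    by_span = select_track(_decision(votes))
    by_count = select_track(_decision(votes), criterion="count")
    assert by_span.selected_track == "center"
    assert by_count.selected_track == "anterior"


def test_track_label_permutation_equivariance():
    rng = np.random.default_rng(6)
    beta = {t: rng.uniform(0, 1, 8) for t in ("center", "anterior", "posterior")}
    hfo = {t: rng.uniform(0, 1, 8) for t in ("center", "anterior", "posterior")}
    model = load_default_model()
    f1 = _features(beta, hfo, normalized=True)
    perm = ("posterior", "center", "anterior")
    f2 = _features({t: beta[t] for t in perm}, {t: hfo[t] for t in perm},
                   normalized=True)
    d1 = select_track(classify_depths(model, f1))
    d2 = select_track(classify_depths(model, f2))
    for t in perm:
        np.testing.assert_array_equal(d1.votes[t], d2.votes[t])
    assert d1.selected_track == d2.selected_track


def test_training_set_accuracy_beats_prior_baseline():
    X, y = _gaussian_classes(np.random.default_rng(7), (1.5, 1.0), n=400)
    model = train_lda(X, y)
    acc = np.mean((model.decision_distance(X) > 0) == y)
    prior = max(y.mean(), 1 - y.mean())
    assert acc >= prior
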