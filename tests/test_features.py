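"""Wavelet decomposition, per-set statistics, information-gain selection."""

import numpy as np
import pytest
import pywt

from fnirsdrive import features as F


def dwt_oracle(x, wav):
    """Literal analysis step: symmetric extension, convolution, ↓2."""
    lo, hi = np.asarray(wav.dec_lo), np.asarray(wav.dec_hi)
    flen = len(lo)
    ext = np.concatenate([x[:flen - 1][::-1], x, x[-(flen - 1):][::-1]])
    n_out = pywt.dwt_coeff_len(len(x), flen, "symmetric")
    return (np.convolve(ext, lo)[flen::2][:n_out],
            np.convolve(ext, hi)[flen::2][:n_out])


def test_zero_signal_gives_zero_coefficients():
    wc = F.db4_decompose(np.zeros(200))
    assert all(np.allclose(s, 0.0) for s in wc.sets())


def test_decomposition_has_five_sets_matching_convolution_oracle():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    wc = F.db4_decompose(x)
    assert len(wc.sets()) == 5
    wav = pywt.Wavelet("db4")
    cur = x
    details_fine_to_coarse = []
    for _ in range(4):
        cur, d = dwt_oracle(cur, wav)
        details_fine_to_coarse.append(d)
    assert np.allclose(wc.approx, cur, atol=1e-10)
    for lvl, d in enumerate(details_fine_to_coarse):
        assert np.allclose(wc.details[lvl], d, atol=1e-10)


def test_perfect_reconstruction():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    wc = F.db4_decompose(x)
    coeffs = [wc.approx] + list(reversed(wc.details))
    rec = pywt.waverec(coeffs, "db4", mode="symmetric")[:200]
    assert np.max(np.abs(rec - x)) / np.max(np.abs(x)) <= 1e-8


def test_energy_preserved_under_periodized_transform():
    rng = np.random.default_rng(2)
    # length divisible by 2^4 so every level stays even under periodization
    x = rng.normal(size=192)
    wc = F.db4_decompose(x, mode="periodization")
    energy = sum(float(np.sum(s**2)) for s in wc.sets())
    assert energy == pytest.approx(float(np.sum(x**2)), rel=1e-10)


def test_too_short_signal_rejected():
    with pytest.raises(ValueError):
        F.db4_decompose(np.zeros(8))


# -- per-set statistics -----------------------------------------------------

def test_constant_set_statistics():
    out = F.featurize_set(np.full(40, 3.0))
    named = dict(zip(F.FEATURE_NAMES, out))
    assert named["std"] == 0 and named["var"] == 0
    assert named["mean"] == 3.0 and named["rms"] == 3.0
    assert named["zero_crossings"] == 0 and named["mean_crossings"] == 0


def test_alternating_signs_hand_counts():
    out = dict(zip(F.FEATURE_NAMES, F.featurize_set(np.array([1., -1., 1., -1.]))))
    assert out["zero_crossings"] == 3
    assert out["mean"] == 0.0
    assert out["rms"] == 1.0


def test_entropy_of_uniform_energy_is_log_m():
    for m in (4, 16, 25):
        c = np.ones(m) * 0.7
        assert F.shannon_entropy(c) == pytest.approx(np.log(m), abs=1e-12)


def test_featurize_rejects_empty_input():
    with pytest.raises(ValueError):
        F.featurize_set(np.array([]))


def test_channel_feature_count_is_60():
    rng = np.random.default_rng(3)
    assert F.channel_features(rng.normal(size=200)).shape == (60,)
    assert len(F.raw_feature_names()) == 60


# -- information gain -------------------------------------------------------

def test_perfect_predictor_gains_one_bit():
    y = np.array([0, 1] * 20)
    assert F.information_gain(y.astype(float), y) == pytest.approx(1.0, abs=1e-12)


def test_independent_feature_below_permutation_null():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 200).astype(bool)
    x = rng.normal(size=200)
    obs = F.information_gain(x, y)
    null = [F.information_gain(rng.permutation(x), y) for _ in range(200)]
    assert obs <= np.quantile(null, 0.95)


def test_contingency_table_matches_hand_arithmetic():
    # x=0: 3 of class 0 and 1 of class 1; x=1: 1 of class 0 and 3 of class 1
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
    h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
    expected = 1.0 - h  # H(Y)=1 bit, H(Y|X)=h in both cells
    got = F.information_gain(x, y, discretized=True)
    assert got == pytest.approx(expected, abs=1e-12)


def test_single_class_labels_score_zero():
    assert F.information_gain(np.arange(10.0), np.zeros(10, dtype=bool)) == 0.0


def test_mutual_info_cross_checks_against_sklearn():
    from sklearn.metrics import mutual_info_score
    rng = np.random.default_rng(5)
    for _ in range(20):
        x = rng.integers(0, 4, 60)
        y = rng.integers(0, 2, 60).astype(bool)
        ours = F.information_gain(x, y, discretized=True)
        theirs = mutual_info_score(x, y) / np.log(2)
        assert ours == pytest.approx(max(theirs, 0.0), abs=1e-8)


# -- selector ---------------------------------------------------------------

def _planted_features(seed=0, n=120):
    """Noise features with 4 label-correlated columns planted per channel."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n).astype(bool)
    X = rng.normal(size=(n, 8, 60))
    planted = {c: sorted(rng.choice(60, 4, replace=False)) for c in range(8)}
    for c, cols in planted.items():
        for j in cols:
            X[:, c, j] += 3.0 * y
    return X, y, planted


def test_selector_recovers_planted_discriminative_features():
    X, y, planted = _planted_features()
    sel = F.fit_selector(X, y)
    assert sel.transform(X).shape == (X.shape[0], 32)
    for c in range(8):
        assert sorted(sel.selected[c].tolist()) == planted[c]


def test_selector_is_deterministic():
    X, y, _ = _planted_features(seed=1)
    a = F.fit_selector(X, y)
    b = F.fit_selector(X, y)
    assert np.array_equal(a.selected, b.selected)


def test_degenerate_channel_selects_by_tie_break_and_is_flagged():
    X, y, _ = _planted_features(seed=2)
    X[:, 3, :] = 1.0  # constant channel: all IG scores 0
    sel = F.fit_selector(X, y)
    assert 3 in sel.degenerate_channels
    assert sel.selected[3].tolist() == [0, 1, 2, 3]  # lowest index wins ties


def test_selector_roundtrip(tmp_path):
    X, y, _ = _planted_features(seed=3)
    sel = F.fit_selector(X, y)
    sel.save(tmp_path / "sel.json")
    back = F.IGSelector.load(tmp_path / "sel.json")
    assert np.array_equal(back.selected, sel.selected)
    assert np.allclose(back.scores, sel.scores)


def test_selector_requires_enough_candidates():
    with pytest.raises(ValueError):
        F.IGSelector(n_select=4).fit(np.zeros((10, 8, 3)), np.zeros(10, dtype=bool))


def test_zero_noise_windows_with_active_response_are_separable(zero_noise_data):
    """After selection, windows during the evoked hemodynamic response are
    linearly separable from resting windows when no noise is present."""
    from sklearn.svm import LinearSVC
    from fnirsdrive import synth as S

    X, slices = zero_noise_data["X"], zero_noise_data["slices"]
    owners = zero_noise_data["owners"]
    episodes = zero_noise_data["episodes"]
    # physiology-aligned label: evoked ΔHbO at the window end above half max
    fs = 50.0
    y_phys = []
    for sl, k in zip(slices, owners):
        ep = episodes[k]
        t = np.arange(int(45 * fs)) / fs
        ev = S.evoked_response(t, ep.risk_intervals, 1.0, fs)
        y_phys.append(ev[min(int(sl.t_end * fs), ev.size - 1)] > 0.5 * ev.max())
    y_phys = np.array(y_phys)
    sel = F.fit_selector(X, y_phys)
    X32 = sel.transform(X)
    svc = LinearSVC(C=1e6, max_iter=100_000).fit(X32, y_phys)
    assert svc.score(X32, y_phys) == 1.0
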