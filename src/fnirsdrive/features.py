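"""Wavelet features and information-gain selection for ΔCOE windows.

Each 4-s, 200-sample ΔCOE window per channel is decomposed with a 4-level
Daubechies-4 (DB4) wavelet transform (symmetric boundary extension),
giving one approximation set and four detail sets.  Twelve statistics per
set yield 60 raw features per channel; the four features with the highest
information gain (mutual information with the binary risk label, in bits)
are kept per channel, for a 32-dimensional vector over 8 channels.

Feature order within a coefficient set (see FEATURE_NAMES):
Shannon entropy of the normalized coefficient-energy distribution (nats),
the 5/25/50/75/95 percentiles, mean, standard deviation, variance, RMS,
and the zero-crossing and mean-crossing counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt

WAVELET = "db4"
LEVELS = 4
PAD_MODE = "symmetric"
N_SETS = LEVELS + 1
FEATURE_NAMES = [
    "shannon_entropy", "p5", "p25", "median", "p75", "p95",
    "mean", "std", "var", "rms", "zero_crossings", "mean_crossings",
]
N_FEATURES_PER_SET = len(FEATURE_NAMES)
N_RAW_PER_CHANNEL = N_SETS * N_FEATURES_PER_SET          # 60
N_SELECTED_PER_CHANNEL = 4
SET_NAMES = ["approx_L4", "detail_L4", "detail_L3", "detail_L2", "detail_L1"]


@dataclass
class WaveletCoeffs:
    """DB4 multilevel decomposition: approximation + 4 detail sets.

    ``details`` is ordered fine-to-coarse: details[0] is level 1,
    details[3] is level 4.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    wavelet: str = WAVELET
    mode: str = PAD_MODE

    def sets(self) -> list[np.ndarray]:
        """[approx L4, detail L4, detail L3, detail L2, detail L1]."""
        return [self.approx] + list(reversed(self.details))


def db4_decompose(signal: np.ndarray, levels: int = LEVELS,
                  mode: str = PAD_MODE) -> WaveletCoeffs:
    """Recursive DB4 analysis (convolve with g/h, downsample by 2) per level."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D window")
    min_len = 2 ** levels
    if x.size < min_len:
        raise ValueError(f"signal too short for {levels}-level decomposition")
    coeffs = pywt.wavedec(x, WAVELET, mode=mode, level=levels)
    approx, *details_coarse_to_fine = coeffs
    return WaveletCoeffs(approx=approx,
                         details=list(reversed(details_coarse_to_fine)),
                         mode=mode)


def shannon_entropy(coeffs: np.ndarray) -> float:
    """Entropy (nats) of the normalized squared-coefficient distribution.

    p_i = c_i² / Σ c², zero-probability terms contribute 0.  An all-zero
    set has entropy 0 by convention.
    """
    c = np.asarray(coeffs, dtype=float)
    energy = c * c
    total = energy.sum()
    if total <= 0:
        return 0.0
    p = energy / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def _crossings(x: np.ndarray, level: float) -> int:
    s = np.sign(x - level)
    s = s[s != 0]  # samples exactly at the level do not break a crossing
    return int(np.count_nonzero(s[1:] != s[:-1]))


def featurize_set(coeffs: np.ndarray) -> np.ndarray:
    """The 12 per-set statistics, in FEATURE_NAMES order."""
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient set")
    pct = np.percentile(c, [5, 25, 50, 75, 95])
    mean = c.mean()
    return np.array([
        shannon_entropy(c),
        pct[0], pct[1], pct[2], pct[3], pct[4],
        mean,
        c.std(),
        c.var(),
        float(np.sqrt(np.mean(c * c))),
        _crossings(c, 0.0),
        _crossings(c, mean),
    ])


def channel_features(window_200: np.ndarray) -> np.ndarray:
    """60 raw features for one channel's 4-s window (5 sets × 12)."""
    wc = db4_decompose(window_200)
    return np.concatenate([featurize_set(s) for s in wc.sets()])


def window_features(coe_window: np.ndarray) -> np.ndarray:
    """(n_channels, 60) raw feature matrix for one 8×200 ΔCOE window."""
    w = np.asarray(coe_window, dtype=float)
    return np.stack([channel_features(w[c]) for c in range(w.shape[0])])


def raw_feature_names() -> list[str]:
    return [f"{s}/{f}" for s in SET_NAMES for f in FEATURE_NAMES]


# ---------------------------------------------------------------------------
# information gain


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def discretize(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile binning of a continuous feature into at most n_bins bins."""
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(x, edges)


def information_gain(feature_column: np.ndarray, labels: np.ndarray,
                     n_bins: int = 10, discretized: bool = False) -> float:
    """I(X;Y) = H(Y) − H(Y|X) in bits, under quantile binning of X.

    Labels must be binary; a single-class label vector yields 0 (there is
    no uncertainty to reduce).  Set ``discretized`` when the feature is
    already categorical.
    """
    x = np.asarray(feature_column)
    y = np.asarray(labels)
    if x.shape != y.shape:
        raise ValueError("feature and labels must align")
    if not np.all(np.isfinite(np.asarray(x, dtype=float))):
        raise ValueError("feature values must be finite")
    hy = _entropy_bits(y)
    if hy == 0.0:
        return 0.0
    bins = x if discretized else discretize(x, n_bins)
    h_cond = 0.0
    n = y.size
    for b in np.unique(bins):
        m = bins == b
        h_cond += (m.sum() / n) * _entropy_bits(y[m])
    return float(max(hy - h_cond, 0.0))


@dataclass
class IGSelector:
    """Per-channel top-4 information-gain feature selection.

    Fit one selector per subject per scenario; ties break toward the
    lowest raw-feature index, making the selection deterministic.
    """

    n_select: int = N_SELECTED_PER_CHANNEL
    n_bins: int = 10
    selected: np.ndarray | None = None        # (n_channels, n_select) indices
    scores: np.ndarray | None = None          # (n_channels, 60) IG scores
    degenerate_channels: list[int] = field(default_factory=list)

    def fit(self, raw_features: np.ndarray, labels: np.ndarray) -> "IGSelector":
        """``raw_features`` is (n_windows, n_channels, 60)."""
        X = np.asarray(raw_features, dtype=float)
        y = np.asarray(labels)
        if X.ndim != 3:
            raise ValueError("expected (n_windows, n_channels, n_raw) features")
        n_win, n_ch, n_raw = X.shape
        if n_raw < self.n_select:
            raise ValueError("fewer candidate features than n_select")
        self.scores = np.zeros((n_ch, n_raw))
        self.selected = np.zeros((n_ch, self.n_select), dtype=int)
        self.degenerate_channels = []
        for c in range(n_ch):
            sc = np.array([information_gain(X[:, c, j], y, self.n_bins)
                           for j in range(n_raw)])
            self.scores[c] = sc
            order = np.lexsort((np.arange(n_raw), -sc))  # score desc, index asc
            self.selected[c] = order[: self.n_select]
            if np.allclose(sc, 0.0):
                self.degenerate_channels.append(c)
        return self

    def transform(self, raw_features: np.ndarray) -> np.ndarray:
        """(n_windows, n_channels, 60) → (n_windows, n_channels*n_select)."""
        if self.selected is None:
            raise RuntimeError("selector not fitted")
        X = np.asarray(raw_features, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.concatenate(
            [X[:, c, self.selected[c]] for c in range(X.shape[1])], axis=1)
        return out[0] if single else out

    def fit_transform(self, raw_features, labels) -> np.ndarray:
        return self.fit(raw_features, labels).transform(raw_features)

    def selected_names(self) -> list[list[str]]:
        names = raw_feature_names()
        return [[names[j] for j in row] for row in self.selected]

    def save(self, path: str | Path) -> None:
        payload = {
            "n_select": self.n_select,
            "n_bins": self.n_bins,
            "pad_mode": PAD_MODE,
            "selected": self.selected.tolist(),
            "scores": self.scores.tolist(),
            "degenerate_channels": self.degenerate_channels,
            "selected_names": self.selected_names(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "IGSelector":
        d = json.loads(Path(path).read_text())
        sel = cls(n_select=d["n_select"], n_bins=d["n_bins"])
        sel.selected = np.asarray(d["selected"], dtype=int)
        sel.scores = np.asarray(d["scores"], dtype=float)
        sel.degenerate_channels = list(d["degenerate_channels"])
        return sel


def fit_selector(raw_features: np.ndarray, labels: np.ndarray,
                 n_bins: int = 10) -> IGSelector:
    """Convenience wrapper returning a fitted :class:`IGSelector`."""
    return IGSelector(n_bins=n_bins).fit(raw_features, labels)


def extract_dataset(slices) -> tuple[np.ndarray, np.ndarray]:
    """Raw features and labels for a list of HemoSlices.

    Returns (n_windows, 8, 60) features and (n_windows,) boolean labels.
    """
    X = np.stack([window_features(s.feature_window()) for s in slices])
    y = np.array([s.label for s in slices], dtype=bool)
    return X, y
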