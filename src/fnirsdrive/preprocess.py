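"""Real-time fNIRS preprocessing chain.

Order of operations, applied to ΔHbO and ΔHbR separately:

1. baseline correction — subtract the per-channel mean of the opening
   resting-state window (default 20 s);
2. cubic-spline resampling onto a uniform 50 Hz grid (device timestamps
   arrive with execution-time jitter);
3. band-pass filtering: the difference of two double-exponential moving
   averages (DEMA, a low-lag IIR low-pass) acts as a MACD-style band-pass,
   followed by a simple moving average (SMA) smoother.

ΔCOE = (ΔHbR − ΔHbO)/2 is computed after filtering and buffered in
rolling 5-s slices (8 channels × 250 samples at 50 Hz); the feature stage
consumes the newest 4 s of each slice.

With λ1 = 0.001 and λ2 = 0.055 at 50 Hz the DEMA-difference band-pass has
−3 dB edges at ≈0.016 and ≈0.90 Hz (see :func:`band_edges`); the 100-point
SMA further attenuates above ≈0.22 Hz and is treated as a smoothing stage,
not as part of the nominal band definition.

All recursive filters run through :func:`scipy.signal.lfilter` with
explicit carried state, so sample-by-sample streaming and one-shot batch
processing produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.signal import lfilter

FS = 50.0
SLICE_S = 5.0
FEATURE_WINDOW = 200  # newest 4 s of a slice feed the feature stage


@dataclass
class FilterParams:
    """MACD band-pass configuration.

    ``lambda1`` (slow) and ``lambda2`` (fast) are the DEMA smoothing
    constants; their difference forms the band-pass.  ``sma_len`` is the
    moving-average smoother length in samples.  ``first_sample_init``
    seeds the DEMA accumulators with the first observed sample (avoids a
    multi-second start-up transient); set False for zero initialization.
    """

    lambda1: float = 0.001
    lambda2: float = 0.055
    sma_len: int = 100
    fs: float = FS
    first_sample_init: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.lambda1 < self.lambda2 < 1):
            raise ValueError("need 0 < lambda1 < lambda2 < 1")
        if self.sma_len < 1:
            raise ValueError("sma_len must be >= 1")


def baseline_correct(series: np.ndarray, fs: float = FS,
                     baseline_window_s: float = 20.0) -> np.ndarray:
    """Subtract the per-channel mean of the opening resting window.

    ``series`` is (..., n_samples); the last axis is time.
    """
    series = np.asarray(series, dtype=float)
    nb = int(round(baseline_window_s * fs))
    if series.shape[-1] <= nb:
        raise ValueError("series shorter than the baseline window")
    mean = series[..., :nb].mean(axis=-1, keepdims=True)
    return series - mean


def resample_50hz(timestamps: np.ndarray, values: np.ndarray,
                  fs: float = FS) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling onto a uniform grid spanning the input range.

    ``values`` is (..., n) along the last axis.  Returns (grid, resampled).
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 samples for cubic resampling")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * fs)) + 1) / fs
    spline = CubicSpline(t, v, axis=-1)
    return grid, spline(grid)


class DemaState:
    """Carried state of one DEMA filter: the two EMA accumulators.

    The accumulators are scipy ``lfilter`` delay-line values, one per
    series (arbitrary leading shape), created lazily on the first block.
    """

    def __init__(self, lam: float, first_sample_init: bool = True):
        if not 0 < lam < 1:
            raise ValueError("lambda must lie in (0, 1)")
        self.lam = lam
        self.first_sample_init = first_sample_init
        self.zi1: np.ndarray | None = None
        self.zi2: np.ndarray | None = None

    def reset(self) -> None:
        self.zi1 = self.zi2 = None

    def process(self, x: np.ndarray) -> np.ndarray:
        """Filter a block (..., n_samples); state persists across blocks."""
        x = np.asarray(x, dtype=float)
        lam = self.lam
        b, a = [lam], [1.0, -(1.0 - lam)]
        if self.zi1 is None:
            seed = x[..., :1] if self.first_sample_init else np.zeros_like(x[..., :1])
            self.zi1 = (1.0 - lam) * seed
            self.zi2 = (1.0 - lam) * seed
        y1, self.zi1 = lfilter(b, a, x, axis=-1, zi=self.zi1)
        y2, self.zi2 = lfilter(b, a, y1, axis=-1, zi=self.zi2)
        return 2.0 * y1 - y2


def dema_step(x_n, lam: float, state: DemaState):
    """Single-sample DEMA update; returns the filtered sample."""
    if state.lam != lam:
        raise ValueError("state was built for a different lambda")
    return state.process(np.asarray(x_n, dtype=float)[..., None])[..., 0]


class MacdFilter:
    """DEMA-difference band-pass plus SMA smoother with persistent state."""

    def __init__(self, params: FilterParams | None = None):
        self.params = params if params is not None else FilterParams()
        p = self.params
        self.slow = DemaState(p.lambda1, p.first_sample_init)
        self.fast = DemaState(p.lambda2, p.first_sample_init)
        self.zi_sma: np.ndarray | None = None

    def reset(self) -> None:
        self.slow.reset()
        self.fast.reset()
        self.zi_sma = None

    def process(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        macd = self.slow.process(x) - self.fast.process(x)
        L = self.params.sma_len
        if L == 1:
            return macd
        b = np.full(L, 1.0 / L)
        if self.zi_sma is None:
            # ring buffer starts empty: zero history before the stream
            self.zi_sma = np.zeros(x.shape[:-1] + (L - 1,))
        y, self.zi_sma = lfilter(b, [1.0], macd, axis=-1, zi=self.zi_sma)
        return y


def macd_bandpass(x: np.ndarray, params: FilterParams | None = None,
                  state: MacdFilter | None = None) -> np.ndarray:
    """One-shot (or stateful, if ``state`` given) band-pass filtering."""
    filt = state if state is not None else MacdFilter(params)
    if state is not None and params is not None and state.params != params:
        raise ValueError("state was built with different parameters")
    return filt.process(x)


def compute_coe(hbr: np.ndarray, hbo: np.ndarray) -> np.ndarray:
    """ΔCOE = (ΔHbR − ΔHbO)/2, the oxygen-exchange brain-activity index."""
    hbr = np.asarray(hbr, dtype=float)
    hbo = np.asarray(hbo, dtype=float)
    if hbr.shape != hbo.shape:
        raise ValueError("hbr and hbo must have identical shapes")
    return (hbr - hbo) / 2.0


# ---------------------------------------------------------------------------
# frequency response


def frequency_response(freqs_hz: np.ndarray, params: FilterParams | None = None,
                       include_smoothing: bool = False) -> np.ndarray:
    """Complex frequency response of the band-pass (optionally with SMA).

    Closed form: an EMA has H(ω) = λ / (1 − (1−λ)e^{−iω}), a DEMA
    2H − H², the band-pass is DEMA(λ1) − DEMA(λ2), and the SMA of length
    L multiplies by (1/L)(1 − e^{−iωL})/(1 − e^{−iω}).
    """
    p = params if params is not None else FilterParams()
    w = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float) / p.fs

    def dema(lam: float) -> np.ndarray:
        E = lam / (1.0 - (1.0 - lam) * np.exp(-1j * w))
        return 2.0 * E - E * E

    H = dema(p.lambda1) - dema(p.lambda2)
    if include_smoothing and p.sma_len > 1:
        L = p.sma_len
        num = 1.0 - np.exp(-1j * w * L)
        den = L * (1.0 - np.exp(-1j * w))
        S = np.where(np.abs(den) < 1e-300, 1.0, num / np.where(den == 0, 1.0, den))
        H = H * S
    return H


def band_edges(params: FilterParams | None = None,
               include_smoothing: bool = False,
               n_grid: int = 200_000) -> tuple[float, float]:
    """−3 dB passband edges (Hz), referenced to the passband maximum.

    By default the edges characterize the DEMA-difference band-pass; pass
    ``include_smoothing=True`` to fold the SMA stage into the response.
    """
    p = params if params is not None else FilterParams()
    f = np.logspace(-5, np.log10(p.fs / 2.0), n_grid)
    mag = np.abs(frequency_response(f, p, include_smoothing))
    i_peak = int(np.argmax(mag))
    thr = mag[i_peak] / np.sqrt(2.0)

    def g(freq: float) -> float:
        return float(np.abs(frequency_response(np.array([freq]), p,
                                               include_smoothing))[0] - thr)

    below_lo = np.nonzero(mag[:i_peak] < thr)[0]
    below_hi = np.nonzero(mag[i_peak:] < thr)[0]
    if below_lo.size == 0 or below_hi.size == 0:
        raise RuntimeError("response has no -3 dB crossing on one side")
    lo = brentq(g, f[below_lo[-1]], f[i_peak])
    hi = brentq(g, f[i_peak], f[i_peak + below_hi[0]])
    return float(lo), float(hi)


def frequency_response_table(params: FilterParams | None = None,
                             include_smoothing: bool = True,
                             n_points: int = 2000) -> np.ndarray:
    """(freq_hz, gain) table for audit, log-spaced up to Nyquist."""
    p = params if params is not None else FilterParams()
    f = np.logspace(-4, np.log10(p.fs / 2.0), n_points)
    gain = np.abs(frequency_response(f, p, include_smoothing))
    return np.column_stack([f, gain])


# ---------------------------------------------------------------------------
# rolling 5-s buffers


@dataclass
class HemoSlice:
    """A 5-s filtered buffer: 8×250 ΔHbO/ΔHbR/ΔCOE at 50 Hz."""

    hbo: np.ndarray
    hbr: np.ndarray
    coe: np.ndarray
    t_end: float          # stream time of the newest sample
    label: bool = False   # button state at t_end (when labels are attached)

    def feature_window(self) -> np.ndarray:
        """The newest 4 s (8×200) of ΔCOE, the feature-stage input."""
        return self.coe[:, -FEATURE_WINDOW:]


class RollingBuffer:
    """Emit 5-s slices from a filtered 50-Hz stream at a fixed stride."""

    def __init__(self, stride_s: float = 0.2, fs: float = FS,
                 slice_s: float = SLICE_S):
        self.n_slice = int(round(slice_s * fs))
        self.stride = int(round(stride_s * fs))
        if self.stride < 1:
            raise ValueError("stride must be at least one sample")
        self.fs = fs
        self._count = 0
        self._next_emit = self.n_slice

    def feed(self, hbo: np.ndarray, hbr: np.ndarray, coe: np.ndarray,
             labels: np.ndarray | None = None):
        """Feed a filtered block (channels × samples); yield HemoSlices."""
        n = hbo.shape[-1]
        start = self._count
        self._count += n
        if not hasattr(self, "_hbo"):
            self._hbo = hbo.copy()
            self._hbr = hbr.copy()
            self._coe = coe.copy()
            self._lab = (labels.copy() if labels is not None
                         else np.zeros(n, dtype=bool))
        else:
            self._hbo = np.concatenate([self._hbo, hbo], axis=-1)[:, -self._keep():]
            self._hbr = np.concatenate([self._hbr, hbr], axis=-1)[:, -self._keep():]
            self._coe = np.concatenate([self._coe, coe], axis=-1)[:, -self._keep():]
            lab = labels if labels is not None else np.zeros(n, dtype=bool)
            self._lab = np.concatenate([self._lab, lab])[-self._keep():]
        out = []
        while self._next_emit <= self._count:
            end = self._next_emit
            rel_end = end - (self._count - self._hbo.shape[-1])
            sl = slice(rel_end - self.n_slice, rel_end)
            out.append(HemoSlice(
                hbo=self._hbo[:, sl].copy(), hbr=self._hbr[:, sl].copy(),
                coe=self._coe[:, sl].copy(),
                t_end=(end - 1) / self.fs,
                label=bool(self._lab[rel_end - 1]),
            ))
            self._next_emit += self.stride
        return out

    def _keep(self) -> int:
        return self.n_slice + self.stride


def process_episode(episode, params: FilterParams | None = None,
                    stride_s: float = 1.0,
                    baseline_window_s: float = 20.0,
                    emit_from_s: float | None = None) -> list[HemoSlice]:
    """Full chain on one episode: resample → baseline → filter → ΔCOE → slices.

    ``emit_from_s`` drops slices ending before that stream time (e.g. the
    resting baseline); default keeps every slice after buffer warm-up.
    """
    p = params if params is not None else FilterParams()
    grid, hbo = resample_50hz(episode.timestamps, episode.hbo, p.fs)
    _, hbr = resample_50hz(episode.timestamps, episode.hbr, p.fs)
    hbo = baseline_correct(hbo, p.fs, baseline_window_s)
    hbr = baseline_correct(hbr, p.fs, baseline_window_s)
    hbo_f = MacdFilter(p).process(hbo)
    hbr_f = MacdFilter(p).process(hbr)
    coe = compute_coe(hbr_f, hbo_f)
    # button labels on the resampled grid (nearest nominal sample)
    idx = np.clip(np.round((grid - episode.timestamps[0]) * episode.fs_nominal)
                  .astype(int), 0, episode.button.size - 1)
    labels = episode.button[idx]
    buf = RollingBuffer(stride_s=stride_s, fs=p.fs)
    slices = buf.feed(hbo_f, hbr_f, coe, labels)
    if emit_from_s is not None:
        slices = [s for s in slices if s.t_end >= emit_from_s]
    return slices
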