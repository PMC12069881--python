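"""Synthetic multichannel fNIRS episodes with known risk structure.

The generator emulates what a continuous-wave prefrontal montage records
while a passenger watches risky driving scenes: per-channel oxy- and
deoxy-hemoglobin concentration changes (ΔHbO, ΔHbR, μM) sampled nominally
at 50 Hz, a canonical double-gamma hemodynamic response evoked by each
risk interval, physiological nuisance components (cardiac, respiratory
and Mayer-wave oscillations, slow drift, white noise), and a boolean
"subjective risk" button channel that follows the risk intervals with a
fixed reaction delay.

Ground truth (the risk intervals) is known exactly, so every downstream
stage — filtering, wavelet features, selection, classification — can be
tested without any recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import gammaln

N_CHANNELS = 8
FS_NOMINAL = 50.0
BASELINE_S = 20.0  # resting-state head used downstream for baseline correction


@dataclass
class NoiseProfile:
    """Additive nuisance components of a continuous-wave fNIRS recording.

    Frequencies are in Hz, amplitudes in μM (peak amplitude of each
    sinusoidal component), ``drift_slope`` in μM/s and ``white_sd`` the
    standard deviation of the white measurement noise.  ``channel_gain``
    scales the evoked response per channel (len = n_channels); defaults
    to all ones.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.05
    respiration_hz: float = 0.25
    respiration_amp: float = 0.05
    mayer_hz: float = 0.1
    mayer_amp: float = 0.03
    drift_slope: float = 0.005
    white_sd: float = 0.05
    channel_gain: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("cardiac", "respiration", "mayer"):
            if getattr(self, f"{name}_amp") < 0:
                raise ValueError(f"{name} amplitude must be >= 0")
            f = getattr(self, f"{name}_hz")
            if not 0 < f < FS_NOMINAL / 2:
                raise ValueError(f"{name} frequency must lie in (0, fs/2)")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")

    def gains(self, n_channels: int) -> np.ndarray:
        if self.channel_gain is None:
            return np.ones(n_channels)
        g = np.asarray(self.channel_gain, dtype=float)
        if g.shape != (n_channels,):
            raise ValueError("channel_gain length must equal n_channels")
        return g

    @classmethod
    def silent(cls) -> "NoiseProfile":
        """All-zero noise: the evoked response alone."""
        return cls(cardiac_amp=0.0, respiration_amp=0.0, mayer_amp=0.0,
                   drift_slope=0.0, white_sd=0.0)


@dataclass
class HemoEpisode:
    """One recording episode: ΔHbO/ΔHbR per channel plus risk labels."""

    timestamps: np.ndarray          # (n,) seconds, strictly increasing
    hbo: np.ndarray                 # (n_channels, n) μM
    hbr: np.ndarray                 # (n_channels, n) μM
    fs_nominal: float
    risk_intervals: list[tuple[float, float]]
    button: np.ndarray              # (n,) bool
    n_channels: int = N_CHANNELS

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        self.button = np.asarray(self.button, dtype=bool)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have identical shape")
        if self.hbo.shape != (self.n_channels, self.timestamps.size):
            raise ValueError("chromophore matrices must be (n_channels, n_samples)")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def to_table(self) -> np.ndarray:
        """(n, 1+2*n_channels+1) array: time, ΔHbO×C, ΔHbR×C, button."""
        return np.column_stack(
            [self.timestamps, self.hbo.T, self.hbr.T, self.button.astype(float)]
        )

    def save_txt(self, path: str | Path) -> None:
        c = self.n_channels
        header = ",".join(
            ["time_s"]
            + [f"hbo_ch{i + 1}" for i in range(c)]
            + [f"hbr_ch{i + 1}" for i in range(c)]
            + ["button"]
        )
        meta = json.dumps(
            {"fs_nominal": self.fs_nominal, "risk_intervals": self.risk_intervals,
             "n_channels": c}
        )
        np.savetxt(path, self.to_table(), delimiter=",",
                   header=header + "\n" + meta, comments="# ")

    @classmethod
    def load_txt(cls, path: str | Path) -> "HemoEpisode":
        with open(path) as fh:
            fh.readline()
            meta = json.loads(fh.readline().lstrip("# ").strip())
        tab = np.loadtxt(path, delimiter=",", comments="#")
        c = int(meta["n_channels"])
        return cls(
            timestamps=tab[:, 0],
            hbo=tab[:, 1:1 + c].T,
            hbr=tab[:, 1 + c:1 + 2 * c].T,
            fs_nominal=float(meta["fs_nominal"]),
            risk_intervals=[tuple(iv) for iv in meta["risk_intervals"]],
            button=tab[:, -1] > 0.5,
            n_channels=c,
        )


def hrf_double_gamma(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    ``peak`` and ``undershoot`` are the gamma shape parameters (unit rate),
    placing the positive peak near 5–6 s and the undershoot near 15–16 s.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x: np.ndarray, a: float) -> np.ndarray:
        return np.exp((a - 1) * np.log(x) - x - gammaln(a))

    h = gpdf(tp, peak) - ratio * gpdf(tp, undershoot)
    out[pos] = h
    m = out.max()
    return out / m if m > 0 else out


def _validate_intervals(risk_intervals, duration_s: float) -> list[tuple[float, float]]:
    ivs = sorted((float(a), float(b)) for a, b in risk_intervals)
    for a, b in ivs:
        if not (0.0 <= a < b <= duration_s):
            raise ValueError(f"risk interval ({a}, {b}) outside [0, {duration_s}]")
    for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError("risk intervals must not overlap")
    return ivs


def evoked_response(t: np.ndarray, risk_intervals, hrf_amplitude: float,
                    fs: float) -> np.ndarray:
    """Boxcar of the risk intervals convolved with the double-gamma HRF."""
    box = np.zeros(t.size)
    for a, b in risk_intervals:
        box[(t >= a) & (t < b)] = 1.0
    kernel = hrf_double_gamma(np.arange(0, 32.0, 1.0 / fs))
    return hrf_amplitude * np.convolve(box, kernel, mode="full")[: t.size] / fs


def generate_episode(
    duration_s: float,
    risk_intervals,
    noise: NoiseProfile | None = None,
    hrf_amplitude: float = 0.5,
    reaction_delay_s: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
    n_channels: int = N_CHANNELS,
    fs: float = FS_NOMINAL,
    timestamp_jitter_s: float = 0.002,
    hbr_ratio: float = -1.0 / 3.0,
    hbr_lag_s: float = 1.0,
) -> HemoEpisode:
    """Simulate one episode of risk-evoked hemodynamics.

    ΔHbO carries the evoked response (boxcar ⊛ HRF, scaled by
    ``hrf_amplitude`` and the per-channel gain); ΔHbR is a negatively
    scaled (``hbr_ratio``), ``hbr_lag_s``-lagged counterpart.  Both get
    independent white noise but share the oscillatory physiological
    components (with per-channel random phases).  The button channel is
    the risk-interval membership shifted by ``reaction_delay_s``.
    Timestamps are jittered around the nominal grid so the resampling
    stage is genuinely exercised; the same seed reproduces the episode
    bitwise.
    """
    if duration_s <= BASELINE_S:
        raise ValueError(f"duration_s must exceed the {BASELINE_S:.0f}-s baseline")
    noise = noise if noise is not None else NoiseProfile()
    ivs = _validate_intervals(risk_intervals, duration_s)
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * fs))
    t_nom = np.arange(n) / fs
    if timestamp_jitter_s > 0:
        jit = rng.uniform(-timestamp_jitter_s, timestamp_jitter_s, n)
        jit[0] = 0.0
        t = np.maximum.accumulate(t_nom + jit)
        t += np.arange(n) * 1e-9  # break exact ties, keep strictly increasing
    else:
        t = t_nom

    ev = evoked_response(t_nom, ivs, hrf_amplitude, fs)
    lag = int(round(hbr_lag_s * fs))
    ev_lag = np.concatenate([np.zeros(lag), ev[: n - lag]]) if lag else ev

    gains = noise.gains(n_channels)
    hbo = np.zeros((n_channels, n))
    hbr = np.zeros((n_channels, n))
    for c in range(n_channels):
        osc = np.zeros(n)
        for f_hz, amp in (
            (noise.cardiac_hz, noise.cardiac_amp),
            (noise.respiration_hz, noise.respiration_amp),
            (noise.mayer_hz, noise.mayer_amp),
        ):
            phase = rng.uniform(0, 2 * np.pi)
            osc += amp * np.sin(2 * np.pi * f_hz * t + phase)
        drift = noise.drift_slope * (t - t.mean()) * rng.choice([-1.0, 1.0])
        hbo[c] = gains[c] * ev + osc + drift + rng.normal(0, noise.white_sd, n)
        hbr[c] = (gains[c] * hbr_ratio * ev_lag + hbr_ratio * osc + hbr_ratio * drift
                  + rng.normal(0, noise.white_sd / 3 if noise.white_sd else 0.0, n))

    button = np.zeros(n, dtype=bool)
    for a, b in ivs:
        button |= (t_nom >= a + reaction_delay_s) & (t_nom < b + reaction_delay_s)

    return HemoEpisode(t, hbo, hbr, fs, ivs, button, n_channels)


@dataclass
class ScenarioProfile:
    """Episode-timing template for one driving scenario.

    Each episode starts with a resting baseline followed by a stable
    driving phase; a single risk event starts at a uniformly random time
    at least ``stable_s`` seconds into the driving phase, mirroring the
    protocol's "10 s of relatively stable driving" before the hazard.
    """

    duration_s: float = 45.0
    stable_s: float = 10.0
    risk_onset_max_s: float = 18.0   # latest onset, measured from driving start
    risk_duration_s: tuple[float, float] = (5.0, 8.0)
    baseline_s: float = BASELINE_S

    def sample_intervals(self, rng: np.random.Generator) -> list[tuple[float, float]]:
        t0 = self.baseline_s + rng.uniform(self.stable_s, self.risk_onset_max_s)
        dur = rng.uniform(*self.risk_duration_s)
        return [(t0, min(t0 + dur, self.duration_s - 1.0))]


def generate_dataset(
    n_episodes: int,
    scenario_profile: ScenarioProfile | None = None,
    seed: int = 0,
    noise: NoiseProfile | None = None,
    **episode_kwargs,
) -> list[HemoEpisode]:
    """Generate ``n_episodes`` episodes with per-episode seeds derived
    deterministically from the master seed."""
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    profile = scenario_profile if scenario_profile is not None else ScenarioProfile()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_episodes)
    episodes = []
    for child in children:
        rng = np.random.default_rng(child)
        ivs = profile.sample_intervals(rng)
        episodes.append(
            generate_episode(profile.duration_s, ivs, noise=noise,
                             seed=child.spawn(1)[0], **episode_kwargs)
        )
    return episodes


def class_balance(episodes: list[HemoEpisode]) -> float:
    """Fraction of button-true samples across a dataset."""
    tot = sum(ep.button.size for ep in episodes)
    pos = sum(int(ep.button.sum()) for ep in episodes)
    return pos / tot if tot else 0.0


def save_dataset(episodes: list[HemoEpisode], outdir: str | Path, seed: int,
                 profile: ScenarioProfile | None = None) -> None:
    """Write episodes as delimited text plus a JSON manifest of parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, ep in enumerate(episodes):
        name = f"episode_{i:03d}.csv"
        ep.save_txt(outdir / name)
        names.append(name)
    manifest = {
        "seed": seed,
        "n_episodes": len(episodes),
        "class_balance": class_balance(episodes),
        "episodes": names,
        "profile": asdict(profile) if profile is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
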