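"""Safety and comfort metrics plus the study's hypothesis-testing recipes.

Safety of a trajectory is summarized by

* the driving risk field: |Ev| = G·R2·M / |r|^{k1} · exp(k2·|v2|·cos θ2),
  a kinetic-energy field around the other agent that decays with the
  relative distance |r| and grows when the other agent moves toward the
  ego vehicle (θ2 is the angle between r and the other agent's velocity
  v2);
* the minimum time-to-collision, TTC = (gap − l) / closing speed, +∞ by
  convention when the gap is opening;

comfort by the mean positive and mean negative jerk (the derivative of
acceleration).  Group comparisons follow the recipe of one-sided Wilcoxon
tests after robust z-score (median / 1.4826·MAD) outlier removal at
|z| > 3; classifier families are compared with a Friedman omnibus test
and Nemenyi post-hoc pairwise p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RiskFieldParams:
    """Constants of the kinetic-energy risk field."""

    G: float = 0.001
    R2: float = 1.0
    M: float = 1705.0
    k1: float = 1.0
    k2: float = 0.05

    def __post_init__(self) -> None:
        if min(self.G, self.R2, self.M, self.k1, self.k2) <= 0:
            raise ValueError("all risk-field constants must be positive")


def risk_field(r, v2: float, theta2: float,
               params: RiskFieldParams | None = None) -> float:
    """Magnitude of the kinetic-energy risk field at relative position r.

    ``r`` may be a scalar distance or a relative-position vector
    (front agent minus ego).  ``v2`` is the other agent's speed and
    ``theta2`` the angle between r and its velocity.
    """
    p = params if params is not None else RiskFieldParams()
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    dist = float(np.linalg.norm(r_arr)) if r_arr.size > 1 else float(abs(r_arr[0]))
    if dist <= 0:
        raise ValueError("relative distance must be nonzero")
    return float(p.G * p.R2 * p.M / dist**p.k1
                 * np.exp(p.k2 * abs(v2) * np.cos(theta2)))


def risk_field_vector(r_vec, v2: float, theta2: float,
                      params: RiskFieldParams | None = None) -> np.ndarray:
    """The field as a vector along the unit relative-position direction."""
    r_vec = np.asarray(r_vec, dtype=float)
    mag = risk_field(r_vec, v2, theta2, params)
    return mag * r_vec / np.linalg.norm(r_vec)


def ttc(gap: float, vehicle_length: float, gap_rate: float) -> float:
    """Time to collision from bumper gap and gap rate.

    TTC = (gap − l) / (−gap_rate) when the gap is closing
    (gap_rate < 0); +∞ when it is constant or opening; exactly 0 at
    contact.  A gap smaller than the vehicle length means the bodies
    already overlap and is rejected.
    """
    if gap < vehicle_length:
        raise ValueError("gap smaller than vehicle length: already overlapping")
    if gap == vehicle_length:
        return 0.0
    if gap_rate >= 0:
        return float("inf")
    return (gap - vehicle_length) / (-gap_rate)


def jerk_stats(accel_series: np.ndarray, dt: float) -> tuple[float, float]:
    """Mean positive and mean negative jerk of an acceleration trace.

    Jerk is the finite-difference derivative (central differences,
    one-sided at the endpoints).  Each sign is averaged over its own
    samples; a sign with no samples contributes 0.
    """
    a = np.asarray(accel_series, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if a.size < 2:
        raise ValueError("need at least 2 acceleration samples")
    jerk = np.gradient(a, dt)
    pos = jerk[jerk > 0]
    neg = jerk[jerk < 0]
    return (float(pos.mean()) if pos.size else 0.0,
            float(neg.mean()) if neg.size else 0.0)


@dataclass
class TrajectoryMetrics:
    max_risk_field: float
    min_ttc: float
    mean_pos_jerk: float
    mean_neg_jerk: float


def trajectory_metrics(gap: np.ndarray, v_front: np.ndarray,
                       accel: np.ndarray, dt: float,
                       vehicle_length: float = 4.5,
                       theta2: float = 0.0,
                       params: RiskFieldParams | None = None,
                       collided: bool = False) -> TrajectoryMetrics:
    """Per-episode safety/comfort summary from logged kinematics.

    ``gap`` is the bumper-to-bumper-equivalent distance trace, ``v_front``
    the other agent's speed trace.  A collision forces min TTC to 0.
    """
    gap = np.asarray(gap, dtype=float)
    v_front = np.asarray(v_front, dtype=float)
    rf = [risk_field(g, v, theta2, params) for g, v in zip(gap, v_front) if g > 0]
    gap_rate = np.gradient(gap, dt)
    ttcs = [ttc(max(g, vehicle_length), vehicle_length, gr)
            for g, gr in zip(gap, gap_rate)]
    min_ttc = 0.0 if collided else float(min(ttcs)) if ttcs else float("inf")
    mpj, mnj = jerk_stats(accel, dt)
    return TrajectoryMetrics(
        max_risk_field=float(max(rf)) if rf else 0.0,
        min_ttc=min_ttc, mean_pos_jerk=mpj, mean_neg_jerk=mnj)


# ---------------------------------------------------------------------------
# hypothesis tests


def robust_zscores(x: np.ndarray) -> np.ndarray:
    """z = (x − median) / (1.4826·MAD); zeros if the MAD vanishes."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def remove_outliers(x: np.ndarray, threshold: float = 3.0):
    """Drop |robust z| > threshold; returns (kept values, n_removed)."""
    x = np.asarray(x, dtype=float)
    keep = np.abs(robust_zscores(x)) <= threshold
    return x[keep], int((~keep).sum())


def compare_episode_metric(group_a: np.ndarray, group_b: np.ndarray,
                           side: str = "greater", paired: bool = False,
                           outlier_threshold: float = 3.0) -> dict:
    """One-sided Wilcoxon comparison after robust-z outlier removal.

    ``side`` is the alternative for group A versus group B ("greater" or
    "less").  Paired mode removes outliers on the pair differences and
    uses the signed-rank test; independent mode cleans each group and
    uses the rank-sum test.
    """
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal length")
        d = a - b
        d, removed = remove_outliers(d, outlier_threshold)
        if d.size < 3:
            raise ValueError("fewer than 3 observations survive outlier removal")
        if np.all(d == 0):
            return {"p": 1.0, "statistic": 0.0, "n_removed": removed,
                    "n_used": int(d.size)}
        stat, p = stats.wilcoxon(d, alternative=side)
    else:
        a, ra = remove_outliers(a, outlier_threshold)
        b, rb = remove_outliers(b, outlier_threshold)
        removed = ra + rb
        if min(a.size, b.size) < 3:
            raise ValueError("fewer than 3 observations survive outlier removal")
        stat, p = stats.mannwhitneyu(a, b, alternative=side)
    return {"p": float(p), "statistic": float(stat), "n_removed": removed,
            "n_used": int(a.size if paired else a.size + b.size)}


def compare_classifiers(ba_matrix: np.ndarray,
                        model_names: list[str] | None = None) -> dict:
    """Friedman omnibus + Nemenyi post-hoc over a subjects×models BA table."""
    X = np.asarray(ba_matrix, dtype=float)
    n, k = X.shape
    if k < 3 or n < 2:
        raise ValueError("need >= 3 models and >= 2 subjects")
    constant_rows = [i for i in range(n) if np.unique(X[i]).size == 1]
    if all(np.ptp(X[i]) == 0 for i in range(n)):
        stat, p = 0.0, 1.0  # every subject ranks the models identically
    else:
        stat, p = stats.friedmanchisquare(*[X[:, j] for j in range(k)])
    ranks = stats.rankdata(-X, axis=1)  # rank 1 = best score
    mean_ranks = ranks.mean(axis=0)
    # Nemenyi: pairwise studentized-range p-values on mean-rank differences
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            pij = stats.studentized_range.sf(q, k, np.inf)
            pmat[i, j] = pmat[j, i] = min(1.0, float(pij))
    names = model_names if model_names is not None else [f"m{j}" for j in range(k)]
    return {
        "friedman_statistic": float(stat), "friedman_p": float(p),
        "mean_ranks": dict(zip(names, mean_ranks.tolist())),
        "nemenyi_p": pd.DataFrame(pmat, index=names, columns=names),
        "constant_rows": constant_rows,
    }


def episode_report(trajectory_log: pd.DataFrame,
                   windows: dict[str, tuple[int, int]] | None = None
                   ) -> pd.DataFrame:
    """Windowed metric tables over a ≥30-episode training log.

    ``trajectory_log`` needs one row per episode with columns
    ``episode``, ``max_risk_field``, ``min_ttc``, ``mean_pos_jerk``,
    ``mean_neg_jerk``.  Default windows are the first, middle and last
    10 episodes.
    """
    log = trajectory_log.sort_values("episode").reset_index(drop=True)
    n = len(log)
    if windows is None:
        if n < 30:
            raise ValueError("need at least 30 episodes for the default windows")
        windows = {"first10": (0, 10), "middle10": (n // 2 - 5, n // 2 + 5),
                   "last10": (n - 10, n)}
    rows = []
    for name, (lo, hi) in windows.items():
        if hi > n:
            raise ValueError(f"window {name} exceeds the {n}-episode log")
        sub = log.iloc[lo:hi]
        rows.append({
            "window": name, "episodes": f"{lo + 1}-{hi}",
            "min_ttc_median": float(sub["min_ttc"].median()),
            "min_ttc_values": sub["min_ttc"].tolist(),
            "max_risk_field_mean": float(sub["max_risk_field"].mean()),
            "mean_pos_jerk": float(sub["mean_pos_jerk"].mean()),
            "mean_neg_jerk": float(sub["mean_neg_jerk"].mean()),
        })
    return pd.DataFrame(rows)
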