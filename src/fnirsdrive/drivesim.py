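"""Longitudinal driving simulator with an IDM fallback controller.

Three single-hazard scenarios, each opening with 10 s of stable driving:

1. autonomous emergency braking — ego and front vehicle both start at
   50 km/h with a 50 m gap; after 10 s the front vehicle decelerates and
   brakes hard once the gap shrinks to a uniformly random 20–40 m;
2. cut-in — ego at 50 km/h, a 40 km/h vehicle 80 m ahead in the adjacent
   lane merges instantaneously at a uniformly random time after 10 s;
3. pedestrian crossing — ego at 40 km/h, a pedestrian 300 m ahead starts
   crossing (1.5 m/s) at a uniformly random time after 10 s; approaching
   within 1.5 m counts as a near miss.

The agent observes the 8-dimensional state (ego velocity x/y, ego
position x/y, front-agent velocity x/y, front-agent position x/y) and
commands a normalized acceleration in [−1, 1], mapped linearly onto
[−8, +3] m/s² (emergency braking to moderate throttle).  Kinematics are
forward-Euler at dt = 0.05 s.  The intelligent driver model (IDM)
supplies the safe fallback action used whenever the fNIRS gate flags
risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evalstats import RiskFieldParams, risk_field, ttc

ACCEL_MIN = -8.0   # m/s^2, emergency braking
ACCEL_MAX = 3.0    # m/s^2
DT = 0.05
EPISODE_CAP_S = 40.0
VEHICLE_LENGTH = 4.5
LANE_OFFSET = 3.5
KMH = 1.0 / 3.6


def accel_from_command(u: float) -> float:
    """Map a normalized command in [−1, 1] onto [ACCEL_MIN, ACCEL_MAX]."""
    u = float(np.clip(u, -1.0, 1.0))
    return ACCEL_MIN + (u + 1.0) * 0.5 * (ACCEL_MAX - ACCEL_MIN)


def command_from_accel(a: float) -> float:
    """Inverse of :func:`accel_from_command`, clipped to [−1, 1]."""
    u = 2.0 * (a - ACCEL_MIN) / (ACCEL_MAX - ACCEL_MIN) - 1.0
    return float(np.clip(u, -1.0, 1.0))


@dataclass
class IDMParams:
    """Intelligent-driver-model parameters (δ is the fixed exponent 4)."""

    v0: float = 50.0 * KMH   # desired speed, m/s
    x0: float = 2.0          # minimum gap, m
    T: float = 1.5           # headway time, s
    a_max: float = 2.0       # maximum acceleration, m/s^2
    b_max: float = 4.0       # maximum (comfortable) deceleration magnitude
    delta: float = 4.0

    def __post_init__(self) -> None:
        if min(self.v0, self.x0, self.T, self.a_max, self.b_max) <= 0:
            raise ValueError("IDM parameters must be positive")


def idm_accel(v: float, gap: float, dv: float, p: IDMParams) -> float:
    """IDM acceleration for ego speed v, bumper gap and closing speed dv.

    dv = v_ego − v_front (positive while closing).  The output is clamped
    to [−b_max, a_max].
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    x_star = p.x0 + max(0.0, v * p.T + v * dv / (2.0 * np.sqrt(p.a_max * p.b_max)))
    a = p.a_max * (1.0 - (v / p.v0) ** p.delta - (x_star / gap) ** 2)
    return float(np.clip(a, -p.b_max, p.a_max))


def idm_free_accel(v: float, p: IDMParams) -> float:
    """Free-flow IDM (no leader)."""
    return float(np.clip(p.a_max * (1.0 - (v / p.v0) ** p.delta),
                         -p.b_max, p.a_max))


@dataclass
class ScenarioConfig:
    scenario: int
    ego_speed: float               # m/s at reset
    front_speed: float             # m/s at reset (pedestrian: 0)
    initial_gap: float             # m (longitudinal, front minus ego)
    trigger_low: float             # lower bound of the randomized trigger
    trigger_high: float            # upper bound
    trigger_is_distance: bool      # True: gap threshold (m); False: time (s)
    pedestrian: bool = False
    clearance: float = 1.5         # near-miss threshold, m (scenario 3)
    dt: float = DT
    episode_cap_s: float = EPISODE_CAP_S
    front_mild_decel: float = 1.0  # scenario 1 pre-trigger deceleration
    front_hard_decel: float = 6.0  # scenario 1 sudden brake
    ped_speed: float = 1.5         # m/s crossing speed
    lane_half_width: float = 1.75

    @classmethod
    def for_scenario(cls, scenario: int) -> "ScenarioConfig":
        if scenario == 1:
            return cls(1, 50 * KMH, 50 * KMH, 50.0, 20.0, 40.0, True)
        if scenario == 2:
            return cls(2, 50 * KMH, 40 * KMH, 80.0, 10.0, 15.0, False)
        if scenario == 3:
            return cls(3, 40 * KMH, 0.0, 300.0, 10.0, 20.0, False,
                       pedestrian=True)
        raise ValueError(f"unknown scenario id {scenario}")


@dataclass
class SimState:
    """Full simulator state; ``vector()`` is the 8-dim agent observation."""

    ego_x: float
    ego_y: float
    ego_vx: float
    ego_vy: float
    front_x: float
    front_y: float
    front_vx: float
    front_vy: float
    t: float = 0.0
    risk_active: bool = False

    def vector(self) -> np.ndarray:
        return np.array([self.ego_vx, self.ego_vy, self.ego_x, self.ego_y,
                         self.front_vx, self.front_vy, self.front_x,
                         self.front_y])


class LongitudinalEnv:
    """reset/step environment for one scenario.

    ``step`` takes the normalized acceleration command and returns
    ``(state_vector, reward, done, info)``; ``info`` carries the true
    gap, relative speed, physical acceleration, per-step jerk, the risk
    field and TTC values, and the ground-truth risk flag (the oracle
    guidance signal).
    """

    def __init__(self, config: ScenarioConfig | int,
                 idm: IDMParams | None = None,
                 reward_weights: dict | None = None,
                 risk_params: RiskFieldParams | None = None):
        self.cfg = (ScenarioConfig.for_scenario(config)
                    if isinstance(config, int) else config)
        self.idm = idm if idm is not None else IDMParams(v0=self.cfg.ego_speed)
        w = {"w_v": 0.1, "w_c": 10.0, "w_j": 0.01, "w_r": 1.0}
        if reward_weights:
            w.update(reward_weights)
        self.w = w
        self.risk_params = risk_params if risk_params is not None else RiskFieldParams()
        self.state: SimState | None = None

    # -- episode control ----------------------------------------------------

    def reset(self, seed: int | None = None) -> np.ndarray:
        self.rng = np.random.default_rng(seed)
        c = self.cfg
        front_y = LANE_OFFSET if c.scenario == 2 else (
            -LANE_OFFSET if c.pedestrian else 0.0)
        self.state = SimState(
            ego_x=0.0, ego_y=0.0, ego_vx=c.ego_speed, ego_vy=0.0,
            front_x=c.initial_gap, front_y=front_y,
            front_vx=c.front_speed, front_vy=0.0)
        self.trigger = float(self.rng.uniform(c.trigger_low, c.trigger_high))
        self.triggered = False
        self.risk_over = False
        self.prev_accel = 0.0
        self.collided = False
        self.near_miss = False
        self._prox_latched = False
        return self.state.vector()

    def _front_agent(self, s: SimState, dt: float) -> None:
        c = self.cfg
        if c.scenario == 1:
            if s.t >= 10.0:
                gap = s.front_x - s.ego_x
                if not self.triggered and gap <= self.trigger:
                    self.triggered = True
                decel = c.front_hard_decel if self.triggered else c.front_mild_decel
                s.front_vx = max(0.0, s.front_vx - decel * dt)
        elif c.scenario == 2:
            if not self.triggered and s.t >= self.trigger:
                self.triggered = True
                s.front_y = 0.0  # instantaneous merge into the ego lane
        elif c.pedestrian:
            if not self.triggered and s.t >= self.trigger:
                self.triggered = True
                s.front_vy = c.ped_speed
            if self.triggered:
                if s.front_y >= LANE_OFFSET:
                    s.front_vy = 0.0

    def _leader_gap(self, s: SimState):
        """(gap, v_front, closing) to the current in-lane leader, or None."""
        c = self.cfg
        if c.pedestrian:
            if not self.triggered or self.risk_over:
                return None
            if s.front_x - s.ego_x <= 0:
                return None
            return (s.front_x - s.ego_x, 0.0, s.ego_vx)
        if c.scenario == 2 and not self.triggered:
            return None
        return (s.front_x - s.ego_x, s.front_vx, s.ego_vx - s.front_vx)

    def idm_action(self) -> float:
        """The fallback controller's normalized action for the current state."""
        s = self.state
        lead = self._leader_gap(s)
        if lead is None:
            a = idm_free_accel(s.ego_vx, self.idm)
        else:
            gap, _, dv = lead
            gap_eff = gap - (0.0 if self.cfg.pedestrian else VEHICLE_LENGTH)
            a = (idm_accel(s.ego_vx, max(gap_eff, 0.1), dv, self.idm)
                 if gap_eff > 0 else -self.idm.b_max)
        return command_from_accel(a)

    def _proximity_risk(self, s: SimState) -> bool:
        """Perceived risk from the ego's own closing behavior: a passenger
        flags danger when the time-to-collision with the current leader
        drops below ~4 s (or the gap is nearly closed) and stays nervous
        until the closing situation is resolved."""
        lead = self._leader_gap(s)
        if lead is None:
            self._prox_latched = False
            return False
        gap, _, dv = lead
        length = 0.0 if self.cfg.pedestrian else VEHICLE_LENGTH
        clear = gap - length
        if clear <= 0.5 or (dv > 0.05 and clear / dv < 4.0):
            self._prox_latched = True
        elif self._prox_latched and (dv <= 0.1 or clear / max(dv, 1e-9) > 8.0):
            self._prox_latched = False
        return self._prox_latched

    def _update_risk(self, s: SimState) -> None:
        c = self.cfg
        if not self.triggered or self.risk_over:
            s.risk_active = self._proximity_risk(s)
            return
        if c.scenario == 1:
            if s.front_vx < 0.05 and (s.ego_vx < 0.05
                                      or s.ego_vx <= s.front_vx + 0.05):
                self.risk_over = True
        elif c.scenario == 2:
            if s.ego_vx <= s.front_vx + 0.1:
                self.risk_over = True
        else:
            cleared = s.front_y > c.lane_half_width + 0.25
            passed = s.ego_x > s.front_x
            stopped = s.ego_vx < 0.05
            if cleared or passed or stopped:
                self.risk_over = True
        s.risk_active = ((self.triggered and not self.risk_over)
                         or self._proximity_risk(s))

    def step(self, accel_command: float, dt: float | None = None):
        if self.state is None:
            raise RuntimeError("call reset() first")
        dt = self.cfg.dt if dt is None else dt
        if dt <= 0:
            raise ValueError("dt must be positive")
        s = self.state
        a = accel_from_command(accel_command)
        # forward Euler; speeds clamped at standstill
        s.ego_x += s.ego_vx * dt
        s.ego_vx = max(0.0, s.ego_vx + a * dt)
        s.front_x += s.front_vx * dt
        s.front_y += s.front_vy * dt
        s.t += dt
        self._front_agent(s, dt)
        self._update_risk(s)

        c = self.cfg
        gap = s.front_x - s.ego_x
        in_same_lane = abs(s.front_y - s.ego_y) < c.lane_half_width
        done = False
        if c.pedestrian:
            dist = float(np.hypot(gap, s.front_y - s.ego_y))
            if self.triggered and dist < c.clearance:
                self.near_miss = True
                self.collided = True
                done = True
        else:
            if in_same_lane and gap <= VEHICLE_LENGTH:
                self.collided = True
                done = True
        if s.t >= c.episode_cap_s:
            done = True
        if self.triggered and self.risk_over and (
                s.ego_vx < 0.05 or c.scenario in (2, 3)):
            done = True  # hazard resolved

        jerk = (a - self.prev_accel) / dt
        reward = self._reward(s, a, jerk)
        info = {
            "t": s.t, "gap": gap, "rel_speed": s.ego_vx - s.front_vx,
            "accel": a, "jerk": jerk, "risk_active": s.risk_active,
            "collided": self.collided, "near_miss": self.near_miss,
            "risk_field": self._risk_field_value(s),
            "ttc": self._ttc_value(s),
            "ego_speed": s.ego_vx, "front_speed": s.front_vx,
        }
        self.prev_accel = a
        return s.vector(), reward, done, info

    # -- reward and metrics -------------------------------------------------

    def _risk_field_value(self, s: SimState) -> float:
        r_vec = np.array([s.ego_x - s.front_x, s.ego_y - s.front_y])
        dist = float(np.linalg.norm(r_vec))
        if dist <= 0:
            dist = 0.1
        v2 = np.array([s.front_vx, s.front_vy])
        speed2 = float(np.linalg.norm(v2))
        if speed2 < 1e-9:
            theta2 = 0.0
        else:
            cosang = float(np.dot(r_vec, v2) / (dist * speed2))
            theta2 = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return risk_field(dist, speed2, theta2, self.risk_params)

    def _ttc_value(self, s: SimState) -> float:
        gap = s.front_x - s.ego_x
        length = 0.0 if self.cfg.pedestrian else VEHICLE_LENGTH
        if gap < length:
            return 0.0
        return ttc(gap, length, -(s.ego_vx - s.front_vx))

    def _reward(self, s: SimState, a: float, jerk: float) -> float:
        w = self.w
        v_ref = self.cfg.ego_speed
        r = w["w_v"] * max(0.0, 1.0 - abs(s.ego_vx - v_ref) / v_ref)
        if self.collided:
            r -= w["w_c"]
        # per-step acceleration increment (jerk*dt), kept bounded
        r -= w["w_j"] * (jerk * self.cfg.dt) ** 2
        r -= w["w_r"] * self._risk_field_value(s) * self.cfg.dt
        return float(r)


def run_idm_episode(env: LongitudinalEnv, seed: int) -> dict:
    """Close the loop with IDM alone; returns the episode summary."""
    env.reset(seed)
    total = 0.0
    steps = 0
    while True:
        _, r, done, info = env.step(env.idm_action())
        total += r
        steps += 1
        if done:
            return {"reward": total, "steps": steps,
                    "collided": info["collided"], "near_miss": info["near_miss"]}
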