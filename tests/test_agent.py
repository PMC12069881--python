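"""TD3 core updates, gated switching, behavior cloning, training protocol."""

import numpy as np
import pytest

from fnirsdrive import agent as A
from fnirsdrive import drivesim as D
from fnirsdrive.nets import MLP, Adam


def tiny_config(**kw):
    base = dict(hidden=(16, 16), batch_size=32, warmup_steps=50,
                explore_noise=0.1, target_smoothing=False)
    base.update(kw)
    return A.TD3Config(**base)


def random_batch(rng, n=16, k=None, a_idm=None):
    return {
        "s": rng.normal(size=(n, A.STATE_DIM)) * A.OBS_SCALE,
        "a": rng.uniform(-1, 1, (n, 1)),
        "r": rng.normal(size=(n, 1)),
        "s2": rng.normal(size=(n, A.STATE_DIM)) * A.OBS_SCALE,
        "done": np.zeros((n, 1)),
        "k": np.full((n, 1), 0.0) if k is None else k,
        "a_idm": rng.uniform(-1, 1, (n, 1)) if a_idm is None else a_idm,
    }


# -- networks ---------------------------------------------------------------

def test_backprop_matches_numerical_gradient():
    rng = np.random.default_rng(0)
    net = MLP([3, 5, 1], tanh_head=True, rng=rng)
    x = rng.normal(size=(4, 3))
    y = rng.normal(size=(4, 1))

    def loss():
        return float(np.mean((net.forward(x) - y) ** 2))

    out = net.forward(x)
    net.zero_grad()
    net.backward(2 * (out - y) / 4)
    analytic = [g.copy() for g in net.gradients()]
    eps = 1e-6
    for p, g in zip(net.parameters(), analytic):
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 6)):  # spot-check several entries
            idx = it.multi_index
            old = p[idx]
            p[idx] = old + eps
            lp = loss()
            p[idx] = old - eps
            lm = loss()
            p[idx] = old
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)
            it.iternext()


def test_input_gradient_from_backward():
    rng = np.random.default_rng(1)
    net = MLP([2, 8, 1], rng=rng)
    x = rng.normal(size=(1, 2))
    net.forward(x)
    gin = net.backward(np.ones((1, 1)))
    eps = 1e-6
    for j in range(2):
        xp, xm = x.copy(), x.copy()
        xp[0, j] += eps
        xm[0, j] -= eps
        num = (net.forward(xp)[0, 0] - net.forward(xm)[0, 0]) / (2 * eps)
        assert gin[0, j] == pytest.approx(num, abs=1e-5)


# -- action selection and switching -----------------------------------------

def test_deterministic_action_repeats_and_respects_bounds():
    ag = A.TD3Agent(tiny_config(), seed=0)
    rng = np.random.default_rng(2)
    states = rng.normal(size=(200, 8)) * A.OBS_SCALE
    acts = [ag.select_action(s) for s in states]
    assert all(-1.0 <= a <= 1.0 for a in acts)
    assert acts[0] == ag.select_action(states[0])


def test_zero_noise_exploration_equals_greedy():
    ag = A.TD3Agent(tiny_config(explore_noise=0.0), seed=0)
    s = np.ones(8)
    assert ag.select_action(s, explore=True) == ag.select_action(s, explore=False)


def test_wrong_state_dimension_rejected():
    ag = A.TD3Agent(tiny_config(), seed=0)
    with pytest.raises(ValueError):
        ag.select_action(np.zeros(7))


def test_switching_is_exact():
    assert A.switch_action(0.7, -0.9, 1) == -0.9
    assert A.switch_action(0.7, -0.9, 0) == 0.7
    with pytest.raises(ValueError):
        A.switch_action(0.5, 0.5, 0.5)


def test_executed_episode_trace_obeys_switching_rule():
    """Replaying a guided episode's logged controller traces through the
    switching equation reproduces the executed actions exactly."""
    env = D.LongitudinalEnv(1)
    ag = A.TD3Agent(tiny_config(), seed=0)
    state = env.reset(seed=0)
    src = A.OracleRiskSource()
    src.attach(env)
    info = None
    rl_trace, idm_trace, k_trace, exec_trace = [], [], [], []
    for _ in range(400):
        k = src.gate(info)
        a_rl = ag.select_action(state, explore=False)
        a_idm = env.idm_action()
        a = A.switch_action(a_rl, a_idm, k)
        rl_trace.append(a_rl)
        idm_trace.append(a_idm)
        k_trace.append(k)
        exec_trace.append(a)
        state, _, done, info = env.step(a)
        if done:
            break
    replay = [(1 - k) * arl + k * aidm
              for arl, aidm, k in zip(rl_trace, idm_trace, k_trace)]
    assert replay == exec_trace


# -- critic update ----------------------------------------------------------

def test_myopic_critic_target_reduces_to_reward():
    ag = A.TD3Agent(tiny_config(gamma=0.0), seed=1)
    rng = np.random.default_rng(3)
    batch = random_batch(rng, n=8)
    s = ag._obs(batch["s"])
    sa = np.hstack([s, batch["a"]])
    expected1 = float(np.mean((ag.critic1(sa) - batch["r"]) ** 2))
    expected2 = float(np.mean((ag.critic2(sa) - batch["r"]) ** 2))
    l1, l2 = ag.critic_update(batch)
    assert l1 == pytest.approx(expected1, rel=1e-12)
    assert l2 == pytest.approx(expected2, rel=1e-12)


def test_single_transition_target_matches_hand_forward_pass():
    ag = A.TD3Agent(tiny_config(gamma=0.9), seed=2)
    rng = np.random.default_rng(4)
    batch = random_batch(rng, n=1)
    s2 = ag._obs(batch["s2"])

    def forward(net, x):
        h = x
        last = len(net.W) - 1
        for i, (w, b) in enumerate(zip(net.W, net.b)):
            h = h @ w + b
            if i < last:
                h = np.maximum(h, 0)
            elif net.tanh_head:
                h = np.tanh(h)
        return h

    a2 = forward(ag.actor_targ, s2)
    q1 = forward(ag.critic1_targ, np.hstack([s2, a2]))
    q2 = forward(ag.critic2_targ, np.hstack([s2, a2]))
    y = float(batch["r"][0, 0]) + 0.9 * min(q1[0, 0], q2[0, 0])
    sa = np.hstack([ag._obs(batch["s"]), batch["a"]])
    exp1 = float((forward(ag.critic1, sa)[0, 0] - y) ** 2)
    l1, _ = ag.critic_update(batch)
    assert l1 == pytest.approx(exp1, rel=1e-10)


def test_identical_twin_critics_share_losses():
    ag = A.TD3Agent(tiny_config(), seed=3)
    ag.critic2.copy_from(ag.critic1)
    ag.critic2_targ.copy_from(ag.critic1_targ)
    batch = random_batch(np.random.default_rng(5))
    l1, l2 = ag.critic_update(batch)
    assert l1 == pytest.approx(l2, rel=1e-12)


def test_target_uses_smaller_critic():
    """Raising one target critic by a constant must not change the
    regression target (the minimum tracks the smaller one)."""
    ag1 = A.TD3Agent(tiny_config(), seed=4)
    ag2 = A.TD3Agent(tiny_config(), seed=4)
    for ag in (ag1, ag2):
        ag.critic2_targ.copy_from(ag.critic1_targ)
    ag2.critic2_targ.b[-1] += 10.0  # larger everywhere, so never the min
    batch = random_batch(np.random.default_rng(6))
    l1a, _ = ag1.critic_update(batch)
    l1b, _ = ag2.critic_update(batch)
    assert l1a == pytest.approx(l1b, rel=1e-12)


def test_empty_batch_rejected():
    ag = A.TD3Agent(tiny_config(), seed=0)
    with pytest.raises(ValueError):
        ag.critic_update(random_batch(np.random.default_rng(0), n=0))


# -- guided actor update ----------------------------------------------------

def test_ungated_batch_reduces_to_plain_td3_actor_step():
    rng = np.random.default_rng(7)
    batch = random_batch(rng, n=16)  # k = 0 everywhere
    plain = A.TD3Agent(tiny_config(bc_weight=0.0), seed=5)
    guided = A.TD3Agent(tiny_config(bc_weight=1.0), seed=5)
    plain.actor_update_guided(batch)
    guided.actor_update_guided(batch)
    for p, q in zip(plain.actor.parameters(), guided.actor.parameters()):
        assert np.allclose(p, q, atol=1e-12)


def test_cloning_term_vanishes_at_its_minimum():
    ag_ref = A.TD3Agent(tiny_config(bc_weight=0.0), seed=6)
    ag_bc = A.TD3Agent(tiny_config(bc_weight=1.0), seed=6)
    rng = np.random.default_rng(8)
    batch = random_batch(rng, n=8, k=np.ones((8, 1)))
    # demonstrations equal to the current policy output: zero cloning grad
    pi = ag_bc.actor(ag_bc._obs(batch["s"]))
    batch["a_idm"] = pi.copy()
    ag_ref.actor_update_guided({**batch})
    ag_bc.actor_update_guided({**batch})
    for p, q in zip(ag_ref.actor.parameters(), ag_bc.actor.parameters()):
        assert np.allclose(p, q, atol=1e-12)


def test_cloning_only_dynamics_converge_to_demonstration():
    ag = A.TD3Agent(tiny_config(bc_weight=1.0, actor_lr=1e-2), seed=7)
    for net in (ag.critic1, ag.critic2):  # freeze Q at a constant
        for p in net.parameters():
            p[...] = 0.0
    rng = np.random.default_rng(9)
    batch = random_batch(rng, n=32, k=np.ones((32, 1)))
    batch["a_idm"] = np.full((32, 1), -0.6)
    for _ in range(400):
        ag.actor_update_guided(batch)
    pi = ag.actor(ag._obs(batch["s"]))
    assert np.max(np.abs(pi - (-0.6))) < 0.05


# -- polyak -----------------------------------------------------------------

def test_polyak_limits_and_hand_value():
    ag = A.TD3Agent(tiny_config(), seed=8)
    before = [p.copy() for p in ag.critic1_targ.parameters()]
    ag.polyak_update(rho=1.0)
    for p, q in zip(before, ag.critic1_targ.parameters()):
        assert np.array_equal(p, q)
    ag.polyak_update(rho=0.0)
    for p, q in zip(ag.critic1.parameters(), ag.critic1_targ.parameters()):
        assert np.array_equal(p, q)
    # scalar toy: targ=1, src=3, rho=0.9 -> 1.2
    ag.critic1.b[-1][...] = 3.0
    ag.critic1_targ.b[-1][...] = 1.0
    ag.polyak_update(rho=0.9)
    assert ag.critic1_targ.b[-1][0] == pytest.approx(1.2)
    with pytest.raises(ValueError):
        ag.polyak_update(rho=1.5)


# -- replay buffer ----------------------------------------------------------

def test_replay_sampling_is_uniform():
    buf = A.ReplayBuffer(capacity=20)
    for i in range(20):
        buf.add(A.Transition(np.full(8, i), 0.0, float(i), np.zeros(8),
                             False, 0, 0.0))
    rng = np.random.default_rng(10)
    counts = np.zeros(20)
    for _ in range(200):
        batch = buf.sample(50, rng)
        idx = batch["r"].astype(int).ravel()
        np.add.at(counts, idx, 1)
    from scipy import stats
    assert stats.chisquare(counts).pvalue > 0.01


def test_empty_buffer_cannot_be_sampled():
    with pytest.raises(ValueError):
        A.ReplayBuffer(10).sample(4, np.random.default_rng(0))


# -- protocol ----------------------------------------------------------------

def protocol(seed, source, pairs=3):
    env = D.LongitudinalEnv(1)
    ag = A.TD3Agent(tiny_config(batch_size=64, warmup_steps=200), seed=seed)
    return A.run_protocol(env, ag, source, n_pairs=pairs, seed=seed)


def test_null_guidance_is_plain_td3_control_arm():
    class AlwaysZero:
        def attach(self, env):
            pass

        def gate(self, info):
            return 0

    a = protocol(0, A.NullRiskSource())
    b = protocol(0, AlwaysZero())
    assert np.allclose(a["reward"].values, b["reward"].values)
    assert (a["gated_steps"] == 0).all()


def test_protocol_alternates_guided_and_test_episodes():
    log = protocol(1, A.OracleRiskSource())
    assert list(log["guided"]) == [True, False] * 3
    assert set(log.columns) >= {"reward", "max_risk_field", "min_ttc",
                                "mean_pos_jerk", "mean_neg_jerk"}


def test_oracle_guidance_gates_risky_steps():
    # at least one guided episode must hand control to IDM during risk
    logs = [protocol(s, A.OracleRiskSource(), pairs=4) for s in (0, 2)]
    gated = sum(log[log["guided"]]["gated_steps"].sum() for log in logs)
    assert gated > 0
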