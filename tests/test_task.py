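"""Unit and property tests for the task simulator and reward rules."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachrl import (
    AgentParams,
    Block,
    ConfigurationError,
    InsufficientDataError,
    InvalidMultiplierError,
    TaskProtocol,
    added_noise_sd,
    baseline_reward,
    clamp_gate,
    closed_loop_reward,
    compute_baseline_sd,
    condition_preset,
    mirrored_session,
    replay_rewards,
    simulate_session,
)
from conftest import STANDARD_AGENT


class TestAddedNoiseSD:
    @pytest.mark.parametrize(
        "sigma_bl, alpha, expected",
        [
            (4.0, 1.0, 0.0),                     # no-noise condition adds nothing
            (1.0, 2.5, math.sqrt(5.25)),
            (2.0, 1.5, 2.0 * math.sqrt(1.25)),
        ],
    )
    def test_examples(self, sigma_bl, alpha, expected):
        assert added_noise_sd(sigma_bl, alpha) == pytest.approx(expected, abs=1e-12)

    def test_alpha_below_one_rejected(self):
        with pytest.raises(InvalidMultiplierError):
            added_noise_sd(4.0, 0.9)

    @given(
        sigma_bl=st.floats(0.1, 50),
        alpha=st.floats(1.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_quadrature_composition(self, sigma_bl, alpha):
        """Baseline SD and the added-noise SD compose to alpha * sigma_bl."""
        sigma_x = added_noise_sd(sigma_bl, alpha)
        total = math.hypot(sigma_bl, sigma_x)
        assert total == pytest.approx(alpha * sigma_bl, rel=1e-9)


class TestBaselineSD:
    def test_constant_angles(self):
        assert compute_baseline_sd([0, 0, 0, 0]) == 0.0

    def test_two_point_sample_sd(self):
        assert compute_baseline_sd([-1, 1]) == pytest.approx(math.sqrt(2))

    def test_monte_carlo_recovers_truth(self, rng):
        draws = rng.normal(0.0, 4.0, size=60)
        # sampling error of an SD estimate at n=60 is ~ sigma/sqrt(2n)
        assert compute_baseline_sd(draws) == pytest.approx(4.0, rel=0.35)

    def test_single_angle_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_baseline_sd([1.0])


class TestRewardRules:
    @pytest.mark.parametrize(
        "theta, target, rewarded",
        [(0.0, 0.0, True), (5.75, 0.0, True), (5.76, 0.0, False)],
    )
    def test_baseline_zone_inclusive(self, theta, target, rewarded):
        assert baseline_reward(theta, target, 5.75) is rewarded

    @pytest.mark.parametrize(
        "theta, running_mean, target, rewarded",
        [
            (-7.0, 0.0, -15.0, True),    # between mean and target
            (+3.0, 0.0, -15.0, False),   # wrong side of the mean
            (-20.7, -10.0, -15.0, True), # within the halfwidth floor past target
            (-20.8, -10.0, -15.0, False),
        ],
    )
    def test_closed_loop_zone(self, theta, running_mean, target, rewarded):
        assert closed_loop_reward(theta, running_mean, target, 5.75) is rewarded

    def test_closed_loop_zone_never_degenerates(self):
        # once the running mean sits on the target, a symmetric zone remains
        assert closed_loop_reward(-15.0 + 5.0, -15.0, -15.0, 5.75)
        assert closed_loop_reward(-15.0 - 5.0, -15.0, -15.0, 5.75)

    @pytest.mark.parametrize(
        "correct, cum_rewarded, cum_trials, expected",
        [
            (False, 0, 0, False),        # clamp never rewards errors
            (True, 33, 100, True),       # 34/101 ~ 0.3366 <= 0.338
            (True, 34, 100, False),      # 35/101 ~ 0.3465 > 0.338
        ],
    )
    def test_clamp_gate_arithmetic(self, correct, cum_rewarded, cum_trials, expected):
        assert clamp_gate(correct, cum_rewarded, cum_trials, 0.338) is expected

    @given(
        outcomes=st.lists(st.booleans(), min_size=1, max_size=300),
        ceiling=st.floats(0.05, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_clamped_rate_never_exceeds_ceiling(self, outcomes, ceiling):
        """Sequentially gated rewards keep the running rate at/below ceiling."""
        cum_r = 0
        for n, correct in enumerate(outcomes):
            if clamp_gate(correct, cum_r, n, ceiling):
                cum_r += 1
            assert cum_r / (n + 1) <= ceiling + 1e-12


class TestProtocol:
    def test_standard_schedule_is_420_trials(self):
        p = TaskProtocol.experiment1()
        assert p.n_trials_total == 420
        assert [b.n_trials for b in p.blocks] == [60, 60, 100, 100, 100]
        assert [b.phase for b in p.blocks] == ["BL1", "BL2", "R1", "washout", "R2"]
        assert p.blocks[2].rotation == -15.0 and p.blocks[4].rotation == 15.0

    def test_invalid_blocks_rejected(self):
        with pytest.raises(ConfigurationError):
            Block("BL1", 0, 0.0)
        with pytest.raises(InvalidMultiplierError):
            TaskProtocol.experiment1(alpha=0.5)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            condition_preset("medium-noise")


class TestSimulateSession:
    def test_trial_count_matches_protocol(self, control_session):
        assert control_session.n_trials == 420

    def test_perfect_agent_full_baseline_reinforcement(self):
        protocol = TaskProtocol(blocks=(Block("BL1", 60, 0.0), Block("BL2", 60, 0.0)))
        agent = AgentParams(0.0, 0.0, 0.0, x0=0.0)
        session = simulate_session(protocol, agent, seed=1)
        assert session.trials["rewarded"].mean() == 1.0

    def test_seed_reproducibility(self, control_protocol):
        a = simulate_session(control_protocol, STANDARD_AGENT, seed=5)
        b = simulate_session(control_protocol, STANDARD_AGENT, seed=5)
        assert a.trials.equals(b.trials)
        assert a.sigma_bl == b.sigma_bl

    def test_no_noise_means_identical_angles(self, control_session):
        t = control_session.trials
        assert (t["theta_noisy_deg"] == t["theta_hand_deg"]).all()

    def test_noise_applied_after_bl1_only(self):
        session = simulate_session(
            condition_preset("high-noise"), STANDARD_AGENT, seed=3
        )
        t = session.trials
        bl1 = t[t["phase"] == "BL1"]
        rest = t[t["phase"] != "BL1"]
        assert (bl1["theta_noisy_deg"] == bl1["theta_hand_deg"]).all()
        assert (rest["theta_noisy_deg"] != rest["theta_hand_deg"]).all()

    def test_update_gating(self, control_session):
        """x moves between trials iff the earlier trial was rewarded, by e."""
        t = control_session.trials
        x = t["sim_internal_estimate_x_deg"].to_numpy()
        e = t["sim_exploration_e_deg"].to_numpy()
        rewarded = t["rewarded"].to_numpy(bool)
        dx = np.diff(x)
        np.testing.assert_allclose(dx[rewarded[:-1]], e[:-1][rewarded[:-1]], atol=1e-12)
        assert np.all(dx[~rewarded[:-1]] == 0.0)

    def test_reward_replay_determinism(self, control_session):
        replayed = replay_rewards(control_session)
        assert (replayed["rewarded"].to_numpy()
                == control_session.trials["rewarded"].to_numpy()).all()
        assert (replayed["hand_in_zone"].to_numpy()
                == control_session.trials["sim_hand_in_zone"].to_numpy()).all()

    def test_replay_matches_under_noise_and_clamp(self):
        for name in ("high-noise", "clamp"):
            session = simulate_session(condition_preset(name), STANDARD_AGENT, seed=9)
            replayed = replay_rewards(session)
            assert (replayed["rewarded"].to_numpy()
                    == session.trials["rewarded"].to_numpy()).all()

    def test_clamp_bound(self):
        session = simulate_session(
            condition_preset("clamp"), AgentParams(0.0, 1.0, 1.0), seed=2
        )
        rewarded = session.trials["rewarded"].to_numpy(float)
        n = np.arange(1, len(rewarded) + 1)
        rate = np.cumsum(rewarded) / n
        assert np.all(rate <= 0.338 + 1.0 / n + 1e-12)

    def test_sign_symmetry(self, control_protocol):
        """Negating x0, targets and all draws negates every angle and
        preserves the reward sequence."""
        total = control_protocol.n_trials_total
        rng = np.random.default_rng(11)
        draws = rng.standard_normal((total, 2))
        z = rng.standard_normal(total)
        agent = AgentParams(3.5, 1.5, 3.0, x0=1.0)
        mirrored_protocol = TaskProtocol.experiment1(rotation_sign_order=+1)
        neg_agent = AgentParams(3.5, 1.5, 3.0, x0=-1.0)

        a = simulate_session(control_protocol, agent, 0, noise_sequence=z,
                             agent_draws=draws)
        b = simulate_session(mirrored_protocol, neg_agent, 0, noise_sequence=-z,
                             agent_draws=-draws)
        np.testing.assert_allclose(
            a.trials["theta_hand_deg"], -b.trials["theta_hand_deg"], atol=1e-12
        )
        np.testing.assert_allclose(
            a.trials["theta_noisy_deg"], -b.trials["theta_noisy_deg"], atol=1e-12
        )
        assert (a.trials["rewarded"] == b.trials["rewarded"]).all()

    def test_mirrored_session_round_trip(self, control_session):
        twice = mirrored_session(mirrored_session(control_session))
        assert twice.trials.equals(control_session.trials)

    def test_shared_noise_sequence_across_conditions(self):
        """Low- and high-noise sessions from one seed reuse one z-sequence."""
        def z_sequence(s):
            t = s.trials[s.trials["phase"] != "BL1"]
            sigma_x = math.sqrt(s.protocol.noise_multiplier ** 2 - 1) * s.sigma_bl
            return ((t["theta_noisy_deg"] - t["theta_hand_deg"]) / sigma_x).to_numpy()

        low = simulate_session(condition_preset("low-noise"), STANDARD_AGENT, seed=4)
        high = simulate_session(condition_preset("high-noise"), STANDARD_AGENT, seed=4)
        np.testing.assert_allclose(z_sequence(low), z_sequence(high), atol=1e-9)

    def test_variance_composition(self):
        """Empirical SD of baseline + scaled noise approaches alpha * sigma_bl."""
        rng = np.random.default_rng(0)
        sigma_bl, alpha, n = 4.0, 2.5, 100_000
        base = rng.normal(0, sigma_bl, n)
        noisy = base + rng.normal(0, added_noise_sd(sigma_bl, alpha), n)
        assert np.std(noisy, ddof=1) == pytest.approx(alpha * sigma_bl, rel=0.03)
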