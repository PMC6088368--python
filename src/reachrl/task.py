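"""Closed-loop reinforcement reach-adaptation task: protocol, reward rules, simulation.

The task is a sequence of point-to-point reaches summarized by a single
endpoint quantity, the reach angle in degrees relative to the
straight-to-target direction (positive = counterclockwise).  A session runs a
fixed block schedule: two 60-trial baseline blocks, then three 100-trial
closed-loop blocks in which the reward zone is rotated +/-15 deg away from the
visual target (rotation, washout, opposite rotation).  Reinforcement is
binary and is assigned to the *noisy* reach angle: an external Gaussian
perturbation can be added to the executed angle before the reward rule is
evaluated, scaled so that total variability equals ``alpha`` times the
subject's baseline SD.

Reward rules
------------
* Baseline blocks: reward iff the (noisy) angle lands within a fixed
  half-width (default 5.75 deg) of the target.
* Closed-loop blocks: reward iff the (noisy) angle lands between the running
  mean of the previous 10 noisy angles and the rotated target, extended one
  half-width beyond the target so the zone keeps a floor width once the mean
  converges onto the target.
* Optional reinforcement clamp: reward for a correct reach is withheld
  whenever awarding it would push the session-wide accumulated reinforcement
  rate above a ceiling (default 0.338 in the clamp condition).

The simulated agent is a reward-gated random walk: it reaches at an internal
estimate ``x`` plus an exploration draw ``e`` (SD conditional on the previous
trial's reward) plus a motor-noise draw ``m`` it cannot sense, and credits
``e`` to ``x`` only after a rewarded trial.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidMultiplierError,
)

__all__ = [
    "Block",
    "TaskProtocol",
    "AgentParams",
    "TrialRecord",
    "Session",
    "RewardAssigner",
    "added_noise_sd",
    "compute_baseline_sd",
    "baseline_reward",
    "closed_loop_reward",
    "clamp_gate",
    "simulate_session",
    "replay_rewards",
    "condition_preset",
    "CONDITION_PRESETS",
    "SESSION_COLUMNS",
]

DEFAULT_ZONE_HALFWIDTH = 5.75  # deg, baseline reward-zone half-width
DEFAULT_WINDOW = 10            # trials in the closed-loop running mean
DEFAULT_ROTATION = 15.0        # deg, magnitude of each reward-zone rotation
DEFAULT_CLAMP_CEILING = 0.338  # accumulated reinforcement-rate ceiling

#: Phases whose reward rule is the fixed baseline zone; everything else is
#: closed-loop.  The first external-noise-free block must be labelled BL1.
BASELINE_PHASES = frozenset({"BL1", "BL2"})

SESSION_COLUMNS = [
    "trial",
    "phase",
    "rotation_deg",
    "theta_hand_deg",
    "theta_noisy_deg",
    "rewarded",
    "sim_hand_in_zone",
    "sim_internal_estimate_x_deg",
    "sim_exploration_e_deg",
    "sim_motor_m_deg",
]


def is_baseline_phase(phase: str) -> bool:
    """True for phases rewarded against the fixed baseline zone."""
    return phase in BASELINE_PHASES


@dataclass(frozen=True)
class Block:
    """One contiguous run of trials with a single rotation and phase label."""

    phase: str
    n_trials: int
    rotation: float  # deg, reward-zone center relative to the visual target

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigurationError(f"block {self.phase!r} needs n_trials > 0")


@dataclass(frozen=True)
class TaskProtocol:
    """Full experimental schedule plus reward-zone and noise parameters.

    Parameters
    ----------
    blocks
        Ordered block schedule. The standard session is
        BL1(60, 0) / BL2(60, 0) / R1(100, +-15) / washout(100, 0) / R2(100, -+15).
    baseline_zone_halfwidth
        Half-width of the baseline reward zone, degrees.
    running_mean_window
        Number of previous noisy reach angles averaged for the closed-loop
        criterion.
    noise_multiplier
        alpha >= 1; total SD of noisy angles is alpha times baseline SD.
    clamp_ceiling
        If set, accumulated session-wide reinforcement rate is clamped to
        this fraction (reward for correct reaches withheld above it).
    rotation_sign_order
        Sign of the first rotation block (+1 = counterclockwise first,
        -1 = clockwise first, the canonical analysis order).
    """

    blocks: tuple[Block, ...]
    baseline_zone_halfwidth: float = DEFAULT_ZONE_HALFWIDTH
    running_mean_window: int = DEFAULT_WINDOW
    noise_multiplier: float = 1.0
    clamp_ceiling: float | None = None
    rotation_sign_order: int = -1

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ConfigurationError("protocol needs at least one block")
        if self.baseline_zone_halfwidth <= 0:
            raise ConfigurationError("baseline_zone_halfwidth must be > 0")
        if self.running_mean_window < 1:
            raise ConfigurationError("running_mean_window must be >= 1")
        if self.noise_multiplier < 1:
            raise InvalidMultiplierError(
                f"noise_multiplier must be >= 1, got {self.noise_multiplier}"
            )
        if self.clamp_ceiling is not None and not (0 < self.clamp_ceiling <= 1):
            raise ConfigurationError("clamp_ceiling must lie in (0, 1]")
        if self.rotation_sign_order not in (-1, 1):
            raise ConfigurationError("rotation_sign_order must be +1 or -1")

    @property
    def n_trials_total(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @classmethod
    def experiment1(
        cls,
        alpha: float = 1.0,
        *,
        rotation_sign_order: int = -1,
        rotation: float = DEFAULT_ROTATION,
        clamp_ceiling: float | None = None,
        **kwargs,
    ) -> "TaskProtocol":
        """The standard 420-trial schedule: 60/60/100/100/100 trials."""
        first = rotation_sign_order * rotation
        blocks = (
            Block("BL1", 60, 0.0),
            Block("BL2", 60, 0.0),
            Block("R1", 100, first),
            Block("washout", 100, 0.0),
            Block("R2", 100, -first),
        )
        return cls(
            blocks,
            noise_multiplier=alpha,
            clamp_ceiling=clamp_ceiling,
            rotation_sign_order=rotation_sign_order,
            **kwargs,
        )


#: Named condition presets: alpha multiplier and optional reinforcement clamp.
CONDITION_PRESETS: dict[str, dict] = {
    "control": {"alpha": 1.0, "clamp_ceiling": None},
    "low-noise": {"alpha": 1.5, "clamp_ceiling": None},
    "high-noise": {"alpha": 2.5, "clamp_ceiling": None},
    "clamp": {"alpha": 1.0, "clamp_ceiling": DEFAULT_CLAMP_CEILING},
}


def condition_preset(name: str, *, rotation_sign_order: int = -1) -> TaskProtocol:
    """Standard-schedule protocol for a named condition preset."""
    try:
        preset = CONDITION_PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown condition {name!r}; choose from {sorted(CONDITION_PRESETS)}"
        ) from None
    return TaskProtocol.experiment1(
        alpha=preset["alpha"],
        clamp_ceiling=preset["clamp_ceiling"],
        rotation_sign_order=rotation_sign_order,
    )


@dataclass(frozen=True)
class AgentParams:
    """The mechanistic agent's variance parameters (all degrees).

    sigma_m is motor noise the agent cannot sense; sigma_e_rewarded /
    sigma_e_unrewarded are exploration SDs conditioned on the previous
    trial's reinforcement; x0 is the initial internal estimate of the
    rewarded direction.
    """

    sigma_m: float
    sigma_e_rewarded: float
    sigma_e_unrewarded: float
    x0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_m", "sigma_e_rewarded", "sigma_e_unrewarded"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def sigma_e(self, prev_rewarded: bool) -> float:
        """Exploration SD in effect given the previous trial's outcome."""
        return self.sigma_e_rewarded if prev_rewarded else self.sigma_e_unrewarded


@dataclass(frozen=True)
class TrialRecord:
    """One trial of a session; hidden-state fields exist for simulations only."""

    trial_index: int
    phase: str
    target_rotation: float
    theta_hand: float
    theta_noisy: float
    rewarded: bool
    hand_in_zone: bool
    internal_estimate_x: float | None = None
    exploration_draw_e: float | None = None
    motor_draw_m: float | None = None


@dataclass
class Session:
    """A simulated or recorded session: protocol plus one row per trial.

    ``trials`` is a DataFrame with the columns in :data:`SESSION_COLUMNS`
    (``sim_*`` columns may be absent for real recordings).  ``sigma_bl`` is
    the baseline reach-angle SD used for external-noise scaling.
    """

    protocol: TaskProtocol
    trials: pd.DataFrame
    sigma_bl: float
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != self.protocol.n_trials_total:
            raise ConfigurationError(
                f"trial count {len(self.trials)} does not match protocol total "
                f"{self.protocol.n_trials_total}"
            )
        if self.sigma_bl < 0:
            raise ConfigurationError("sigma_bl must be >= 0")
        if self.protocol.noise_multiplier > 1 and self.sigma_bl <= 0:
            raise ConfigurationError("sigma_bl must be > 0 when noise is added")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def phase_frame(self, phase: str) -> pd.DataFrame:
        """Rows of one phase, in trial order."""
        return self.trials[self.trials["phase"] == phase]

    def block_rotation(self, phase: str) -> float:
        for b in self.protocol.blocks:
            if b.phase == phase:
                return b.rotation
        raise KeyError(phase)

    def records(self) -> Iterator[TrialRecord]:
        has_sim = "sim_internal_estimate_x_deg" in self.trials.columns
        for row in self.trials.itertuples(index=False):
            yield TrialRecord(
                trial_index=int(row.trial),
                phase=str(row.phase),
                target_rotation=float(row.rotation_deg),
                theta_hand=float(row.theta_hand_deg),
                theta_noisy=float(row.theta_noisy_deg),
                rewarded=bool(row.rewarded),
                hand_in_zone=bool(getattr(row, "sim_hand_in_zone", False)),
                internal_estimate_x=(
                    float(row.sim_internal_estimate_x_deg) if has_sim else None
                ),
                exploration_draw_e=(
                    float(row.sim_exploration_e_deg) if has_sim else None
                ),
                motor_draw_m=float(row.sim_motor_m_deg) if has_sim else None,
            )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def added_noise_sd(sigma_bl: float, alpha: float) -> float:
    """SD of the external noise that lifts total SD to ``alpha * sigma_bl``.

    Baseline variability and the injected noise add in quadrature, so the
    required noise SD is ``sqrt(alpha**2 - 1) * sigma_bl``.
    """
    if alpha < 1:
        raise InvalidMultiplierError(f"alpha must be >= 1, got {alpha}")
    if sigma_bl <= 0:
        raise ConfigurationError(f"sigma_bl must be > 0, got {sigma_bl}")
    return math.sqrt(alpha * alpha - 1.0) * sigma_bl


def compute_baseline_sd(baseline_angles: Sequence[float]) -> float:
    """Sample SD (n-1 denominator) of first-baseline reach angles."""
    angles = np.asarray(baseline_angles, dtype=float)
    if angles.size < 2:
        raise InsufficientDataError("need at least 2 baseline angles")
    return float(np.std(angles, ddof=1))


def baseline_reward(theta_noisy: float, target: float, halfwidth: float) -> bool:
    """Baseline rule: reward iff within ``halfwidth`` of the target (inclusive)."""
    if halfwidth <= 0:
        raise ConfigurationError("halfwidth must be > 0")
    return abs(theta_noisy - target) <= halfwidth


def closed_loop_reward(
    theta_noisy: float, running_mean: float, target: float, halfwidth: float
) -> bool:
    """Closed-loop rule: reward iff the angle lies between the running mean
    and the target, extended ``halfwidth`` beyond the target on the far side.

    The extension gives the zone a floor width, so it never collapses once
    the running mean converges onto the target.  If the mean sits exactly on
    the target the zone degenerates to the symmetric baseline zone.
    """
    if halfwidth <= 0:
        raise ConfigurationError("halfwidth must be > 0")
    d = target - running_mean
    if d > 0:
        lo, hi = running_mean, target + halfwidth
    elif d < 0:
        lo, hi = target - halfwidth, running_mean
    else:
        lo, hi = target - halfwidth, target + halfwidth
    return lo <= theta_noisy <= hi


def clamp_gate(
    correct: bool, cum_rewarded: int, cum_trials: int, ceiling: float
) -> bool:
    """Reinforcement-clamp gate on one trial.

    ``cum_rewarded`` / ``cum_trials`` count all previous trials from session
    start.  Incorrect reaches are never rewarded; a correct reach is rewarded
    only if awarding it keeps the accumulated rate at or below ``ceiling``.
    """
    if not (0 < ceiling <= 1):
        raise ConfigurationError("ceiling must lie in (0, 1]")
    if cum_trials < 0 or cum_rewarded < 0 or cum_rewarded > cum_trials:
        raise ConfigurationError("invalid cumulative counts")
    if not correct:
        return False
    return (cum_rewarded + 1) / (cum_trials + 1) <= ceiling


class RewardAssigner:
    """Stateful reward-rule evaluator for one pass through a session.

    Keeps the running-mean window (over noisy angles, carried across block
    boundaries) and the cumulative clamp counts.  ``zone_test`` evaluates the
    current zone without mutating state, so the executed (noise-free) angle
    can be classified against the same zone the noisy angle is rewarded on.
    """

    def __init__(self, protocol: TaskProtocol):
        self.protocol = protocol
        self._window: deque[float] = deque(maxlen=protocol.running_mean_window)
        self._cum_rewarded = 0
        self._cum_trials = 0

    def running_mean(self, rotation: float) -> float:
        # Before any history exists the criterion falls back to the zone
        # center itself (standard schedules always have baseline history).
        if not self._window:
            return float(rotation)
        return float(np.mean(self._window))

    def zone_test(self, theta: float, phase: str, rotation: float) -> bool:
        hw = self.protocol.baseline_zone_halfwidth
        if is_baseline_phase(phase):
            return baseline_reward(theta, rotation, hw)
        return closed_loop_reward(theta, self.running_mean(rotation), rotation, hw)

    def step(self, theta_noisy: float, phase: str, rotation: float) -> tuple[bool, bool]:
        """Assign reward for one trial and advance state.

        Returns ``(rewarded, in_zone)`` where ``in_zone`` is the pre-clamp
        zone outcome of the noisy angle.
        """
        in_zone = self.zone_test(theta_noisy, phase, rotation)
        if self.protocol.clamp_ceiling is not None:
            rewarded = clamp_gate(
                in_zone, self._cum_rewarded, self._cum_trials,
                self.protocol.clamp_ceiling,
            )
        else:
            rewarded = in_zone
        self._window.append(float(theta_noisy))
        self._cum_trials += 1
        self._cum_rewarded += int(rewarded)
        return rewarded, in_zone


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _seed_int(seed: int) -> int:
    seed = int(seed)
    if seed < 0:
        raise ConfigurationError("seed must be non-negative")
    return seed


def simulate_session(
    protocol: TaskProtocol,
    agent: AgentParams,
    seed: int,
    *,
    sigma_bl: float | None = None,
    noise_sequence: np.ndarray | None = None,
    agent_draws: np.ndarray | None = None,
) -> Session:
    """Simulate one session of the closed-loop task.

    Per trial the agent draws exploration ``e ~ N(0, sigma_e(prev reward)^2)``
    and motor noise ``m ~ N(0, sigma_m^2)``, executes
    ``theta_hand = x + e + m``, and the environment forms
    ``theta_noisy = theta_hand + sigma_x * z`` where ``z`` comes from a single
    standard-normal sequence shared by all noise conditions (scaled by the
    session's baseline SD) and ``sigma_x`` follows :func:`added_noise_sd`.
    No external noise is applied in BL1.  Reward follows the phase's rule,
    optionally clamped; the internal estimate updates ``x <- x + e`` only
    after rewarded trials.

    Parameters
    ----------
    sigma_bl
        Baseline SD override for noise scaling; defaults to the sample SD of
        the session's own BL1 reach angles.
    noise_sequence
        Standard-normal external-noise sequence covering every trial after
        BL1; pass the same array across conditions to share the noise draws.
    agent_draws
        Standard-normal draws of shape ``(n_trials, 2)`` for (e, m); exposed
        so matched or sign-flipped sessions can be constructed exactly.
    """
    seed = _seed_int(seed)
    total = protocol.n_trials_total
    rng_agent = np.random.default_rng([seed, 11])
    rng_noise = np.random.default_rng([seed, 29])

    if agent_draws is None:
        agent_draws = rng_agent.standard_normal((total, 2))
    else:
        agent_draws = np.asarray(agent_draws, dtype=float)
        if agent_draws.shape != (total, 2):
            raise ConfigurationError(
                f"agent_draws must have shape ({total}, 2)"
            )

    n_after_bl1 = sum(b.n_trials for b in protocol.blocks if b.phase != "BL1")
    if noise_sequence is None:
        z_noise = rng_noise.standard_normal(n_after_bl1)
    else:
        z_noise = np.asarray(noise_sequence, dtype=float)
        if z_noise.size < n_after_bl1:
            raise ConfigurationError(
                f"noise_sequence must supply >= {n_after_bl1} values"
            )

    assigner = RewardAssigner(protocol)
    x = float(agent.x0)
    prev_rewarded = True  # pre-session context: treated as rewarded
    bl1_hand: list[float] = []
    sigma_bl_val = sigma_bl
    sigma_x: float | None = None

    rows = []
    t = 0
    i_noise = 0
    for block in protocol.blocks:
        for _ in range(block.n_trials):
            se = agent.sigma_e(prev_rewarded)
            e = se * agent_draws[t, 0]
            m = agent.sigma_m * agent_draws[t, 1]
            theta_hand = x + e + m

            if block.phase == "BL1":
                theta_noisy = theta_hand
                bl1_hand.append(theta_hand)
            else:
                if sigma_x is None:
                    if sigma_bl_val is None:
                        if len(bl1_hand) >= 2:
                            sigma_bl_val = compute_baseline_sd(bl1_hand)
                        elif protocol.noise_multiplier > 1:
                            raise ConfigurationError(
                                "sigma_bl required: no BL1 block to estimate it from"
                            )
                        else:
                            sigma_bl_val = 0.0
                    if protocol.noise_multiplier > 1:
                        sigma_x = added_noise_sd(
                            sigma_bl_val, protocol.noise_multiplier
                        )
                    else:
                        sigma_x = 0.0
                theta_noisy = theta_hand + sigma_x * z_noise[i_noise]
                i_noise += 1

            hand_in_zone = assigner.zone_test(theta_hand, block.phase, block.rotation)
            rewarded, _ = assigner.step(theta_noisy, block.phase, block.rotation)

            rows.append(
                (t + 1, block.phase, block.rotation, theta_hand, theta_noisy,
                 int(rewarded), int(hand_in_zone), x, e, m)
            )
            if rewarded:
                x = x + e
            prev_rewarded = bool(rewarded)
            t += 1

    if sigma_bl_val is None:
        sigma_bl_val = compute_baseline_sd(bl1_hand) if len(bl1_hand) >= 2 else 0.0

    trials = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    return Session(protocol, trials, float(sigma_bl_val), seed)


def replay_rewards(session: Session) -> pd.DataFrame:
    """Recompute rewards and zone membership from recorded noisy angles.

    Rewards are a deterministic function of the noisy-angle sequence and the
    protocol, so replaying a recorded session must reproduce its reward
    column exactly; this also reconstructs ``hand_in_zone`` for recordings
    that lack the simulated hidden columns.
    """
    assigner = RewardAssigner(session.protocol)
    rewarded = np.empty(session.n_trials, dtype=int)
    hand_in_zone = np.empty(session.n_trials, dtype=int)
    for i, row in enumerate(session.trials.itertuples(index=False)):
        phase, rot = str(row.phase), float(row.rotation_deg)
        hand_in_zone[i] = int(assigner.zone_test(float(row.theta_hand_deg), phase, rot))
        r, _ = assigner.step(float(row.theta_noisy_deg), phase, rot)
        rewarded[i] = int(r)
    return pd.DataFrame(
        {"rewarded": rewarded, "hand_in_zone": hand_in_zone},
        index=session.trials.index,
    )


def mirrored_session(session: Session) -> Session:
    """Sign-flipped copy: negate every angle, preserve rewards and labels."""
    trials = session.trials.copy()
    for col in (
        "rotation_deg", "theta_hand_deg", "theta_noisy_deg",
        "sim_internal_estimate_x_deg", "sim_exploration_e_deg", "sim_motor_m_deg",
    ):
        if col in trials.columns:
            trials[col] = -trials[col]
    blocks = tuple(
        Block(b.phase, b.n_trials, -b.rotation) for b in session.protocol.blocks
    )
    protocol = replace(
        session.protocol,
        blocks=blocks,
        rotation_sign_order=-session.protocol.rotation_sign_order,
    )
    return Session(protocol, trials, session.sigma_bl, session.rng_seed)
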