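"""Behavioral summary statistics for closed-loop reinforcement sessions.

All angle-valued learning measures are reported in canonical sign: positive
means movement in the direction that counters the block's rotation, so
learning reads as a positive number regardless of rotation direction.
Sessions themselves can be canonicalized to a single clockwise-then-
counterclockwise rotation order with :func:`canonicalize_signs`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, EmptySelectionError, InsufficientDataError
from .task import Session, mirrored_session, replay_rewards

__all__ = [
    "CATEGORY_LABELS",
    "BehaviorSummary",
    "reinforcement_rate",
    "early_learning_slope",
    "total_learning",
    "delta_by_feedback",
    "goodness_of_fit_r2",
    "canonicalize_signs",
    "block_means",
    "hand_in_zone_series",
    "summarize_session",
]

#: Feedback-by-accuracy category labels for the trial-to-trial change analysis.
CATEGORY_LABELS = (
    "Rewarded-In zone",
    "Rewarded-Out zone",
    "Unrewarded-Out zone",
    "Unrewarded-In zone",
)

EARLY_WINDOW = 40  # trials for the early-learning regression
FINAL_WINDOW = 40  # trials for block means and total learning


@dataclass
class BehaviorSummary:
    """All per-session summary statistics in one bundle.

    Learning measures are per rotation block; ``delta_by_category`` maps the
    four feedback-by-accuracy labels (plus "Rewarded"/"Unrewarded"
    collapses) to mean absolute reach-angle changes, with ``None`` marking
    categories that contained no trials.
    """

    reinforcement_rate: float                       # percent, whole session
    early_learning_slope: dict[str, float]          # deg/trial per rotation block
    total_learning: dict[str, float]                # deg per rotation block
    block_means: dict[str, float]                   # deg, final-40 mean per block
    delta_by_category: dict[str, float | None]      # mean |d theta| per category
    category_counts: dict[str, int]


def reinforcement_rate(
    session: Session, phases: Sequence[str] | None = None
) -> float:
    """Percentage of reinforced trials, optionally restricted to phases."""
    trials = session.trials
    if phases is not None:
        trials = trials[trials["phase"].isin(list(phases))]
    if len(trials) == 0:
        raise EmptySelectionError(f"no trials in phases {phases!r}")
    return float(100.0 * trials["rewarded"].mean())


def _rotation_block(session: Session, phase: str) -> tuple[pd.DataFrame, float]:
    sub = session.phase_frame(phase)
    if len(sub) == 0:
        raise EmptySelectionError(f"no trials in phase {phase!r}")
    rotation = session.block_rotation(phase)
    if rotation == 0:
        raise ContractError(f"phase {phase!r} is not a rotation block")
    return sub, rotation


def early_learning_slope(session: Session, rotation_block: str = "R1") -> float:
    """OLS slope of reach angle on trial index over the block's first 40
    trials, degrees/trial, canonical sign (countering the rotation > 0)."""
    sub, rotation = _rotation_block(session, rotation_block)
    if len(sub) < EARLY_WINDOW:
        raise InsufficientDataError(
            f"{rotation_block} has {len(sub)} trials; need >= {EARLY_WINDOW}"
        )
    y = sub["theta_hand_deg"].to_numpy(dtype=float)[:EARLY_WINDOW]
    t = np.arange(EARLY_WINDOW, dtype=float)
    slope = float(np.polyfit(t, y, 1)[0])
    return slope * float(np.sign(rotation))


def total_learning(
    session: Session,
    rotation_block: str = "R1",
    baseline_phase: str = "BL2",
) -> float:
    """Mean of the block's final 40 trials minus the baseline reference
    (final 40 trials of BL2 by default), canonical sign."""
    sub, rotation = _rotation_block(session, rotation_block)
    if len(sub) < FINAL_WINDOW:
        raise InsufficientDataError(
            f"{rotation_block} has {len(sub)} trials; need >= {FINAL_WINDOW}"
        )
    base = session.phase_frame(baseline_phase)
    if len(base) == 0:
        raise ContractError(f"baseline phase {baseline_phase!r} missing")
    final = sub["theta_hand_deg"].to_numpy(dtype=float)[-FINAL_WINDOW:]
    base_ref = base["theta_hand_deg"].to_numpy(dtype=float)[-FINAL_WINDOW:]
    return float((final.mean() - base_ref.mean()) * np.sign(rotation))


def block_means(session: Session, final_n: int = FINAL_WINDOW) -> dict[str, float]:
    """Mean reach angle over the final ``final_n`` trials of each block."""
    out = {}
    for b in session.protocol.blocks:
        sub = session.phase_frame(b.phase)
        out[b.phase] = float(
            sub["theta_hand_deg"].to_numpy(dtype=float)[-final_n:].mean()
        )
    return out


def hand_in_zone_series(session: Session) -> np.ndarray:
    """Per-trial flag: executed (noise-free) reach angle inside the reward
    zone.  Uses the simulator's recorded column when present, otherwise
    reconstructs the zone state from the noisy-angle series."""
    if "sim_hand_in_zone" in session.trials.columns:
        return session.trials["sim_hand_in_zone"].to_numpy(dtype=bool)
    return replay_rewards(session)["hand_in_zone"].to_numpy(dtype=bool)


def delta_by_feedback(session: Session) -> tuple[dict[str, float | None], dict[str, int]]:
    """Mean absolute reach-angle change following each feedback category.

    Trial t (with a successor in the same block) contributes
    ``|theta_hand(t+1) - theta_hand(t)|`` to the category given by trial t's
    reinforcement and whether the executed reach was in the zone.  Pairs
    spanning block boundaries are excluded.  Returns (means, counts); a
    category with no trials maps to ``None``.
    """
    trials = session.trials
    theta = trials["theta_hand_deg"].to_numpy(dtype=float)
    rewarded = trials["rewarded"].to_numpy(dtype=bool)
    in_zone = hand_in_zone_series(session)
    phase = trials["phase"].to_numpy()

    same_block = phase[1:] == phase[:-1]
    deltas = np.abs(np.diff(theta))

    label_of = {
        (True, True): "Rewarded-In zone",
        (True, False): "Rewarded-Out zone",
        (False, False): "Unrewarded-Out zone",
        (False, True): "Unrewarded-In zone",
    }
    buckets: dict[str, list[float]] = {lab: [] for lab in CATEGORY_LABELS}
    buckets["Rewarded"] = []
    buckets["Unrewarded"] = []
    for t in range(len(theta) - 1):
        if not same_block[t]:
            continue
        lab = label_of[(bool(rewarded[t]), bool(in_zone[t]))]
        buckets[lab].append(deltas[t])
        buckets["Rewarded" if rewarded[t] else "Unrewarded"].append(deltas[t])

    means = {
        lab: (float(np.mean(vals)) if vals else None)
        for lab, vals in buckets.items()
    }
    counts = {lab: len(vals) for lab, vals in buckets.items()}
    return means, counts


def goodness_of_fit_r2(
    mean_data: Sequence[float], mean_model: Sequence[float]
) -> float:
    """R^2 of a model-predicted mean trial series against the data mean:
    ``1 - SS_res / SS_tot``."""
    data = np.asarray(mean_data, dtype=float)
    model = np.asarray(mean_model, dtype=float)
    if data.shape != model.shape or data.size < 2:
        raise ContractError("series must have equal length >= 2")
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0:
        raise ContractError("R^2 undefined for zero-variance data")
    ss_res = float(np.sum((data - model) ** 2))
    return 1.0 - ss_res / ss_tot


def canonicalize_signs(session: Session) -> Session:
    """Re-sign a session so rotations read clockwise-then-counterclockwise.

    If the first rotated block is already clockwise (negative), the session
    is returned as an unchanged copy; otherwise every angle (and the
    protocol's rotations) is negated.  Rewards are sign-free and untouched.
    Applying the function twice is the identity.
    """
    first_rotation = next(
        (b.rotation for b in session.protocol.blocks if b.rotation != 0), None
    )
    if first_rotation is None:
        raise ContractError("session has no rotation block; order unknown")
    if first_rotation < 0:
        return Session(
            session.protocol, session.trials.copy(), session.sigma_bl,
            session.rng_seed,
        )
    return mirrored_session(session)


def summarize_session(session: Session) -> BehaviorSummary:
    """Compute the full behavioral summary for one session."""
    canon = canonicalize_signs(session)
    rotation_phases = [
        b.phase for b in canon.protocol.blocks if b.rotation != 0
    ]
    slopes = {p: early_learning_slope(canon, p) for p in rotation_phases}
    learning = {p: total_learning(canon, p) for p in rotation_phases}
    means, counts = delta_by_feedback(canon)
    return BehaviorSummary(
        reinforcement_rate=reinforcement_rate(canon),
        early_learning_slope=slopes,
        total_learning=learning,
        block_means=block_means(canon),
        delta_by_category=means,
        category_counts=counts,
    )
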