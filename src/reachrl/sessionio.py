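"""Session-file and configuration I/O.

Sessions are stored as plain CSV: a short block of ``#``-prefixed metadata
lines (session-level fields and the protocol's scalar parameters) followed
by a header row and one row per trial.  Angles are written with 17
significant digits so write-then-read round trips are exact at float64
precision.  Simulation-only hidden-state columns carry a ``sim_`` prefix
and may be absent in real recordings.

Protocol/agent configuration is a YAML mapping mirroring the
:class:`~reachrl.task.TaskProtocol` and :class:`~reachrl.task.AgentParams`
field names.
"""
from __future__ import annotations

import io
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .task import AgentParams, Block, Session, TaskProtocol

__all__ = [
    "write_session",
    "read_session",
    "session_to_csv_text",
    "protocol_from_mapping",
    "agent_from_mapping",
    "load_config",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"
_FORMAT_TAG = "reachrl-session-v1"


def _fmt(value: float | None) -> str:
    if value is None:
        return "none"
    return FLOAT_FORMAT % value


def session_to_csv_text(session: Session) -> str:
    """Serialize a session to CSV text (metadata comments + trial table)."""
    p = session.protocol
    lines = [
        f"# format = {_FORMAT_TAG}",
        f"# sigma_bl = {_fmt(session.sigma_bl)}",
        f"# rng_seed = {'none' if session.rng_seed is None else int(session.rng_seed)}",
        f"# baseline_zone_halfwidth = {_fmt(p.baseline_zone_halfwidth)}",
        f"# running_mean_window = {p.running_mean_window}",
        f"# noise_multiplier = {_fmt(p.noise_multiplier)}",
        f"# clamp_ceiling = {_fmt(p.clamp_ceiling)}",
        f"# rotation_sign_order = {p.rotation_sign_order}",
    ]
    buf = io.StringIO()
    session.trials.to_csv(buf, index=False, float_format=FLOAT_FORMAT)
    return "\n".join(lines) + "\n" + buf.getvalue()


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(session_to_csv_text(session))
    return path


def _parse_meta(text: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _blocks_from_trials(trials: pd.DataFrame) -> tuple[Block, ...]:
    """Reconstruct the block schedule from consecutive phase runs."""
    phases = trials["phase"].to_numpy()
    rotations = trials["rotation_deg"].to_numpy(dtype=float)
    blocks: list[Block] = []
    start = 0
    for i in range(1, len(phases) + 1):
        if i == len(phases) or phases[i] != phases[start]:
            blocks.append(
                Block(str(phases[start]), i - start, float(rotations[start]))
            )
            start = i
    return tuple(blocks)


def read_session(path: str | Path) -> Session:
    """Read a session CSV (with or without the ``sim_`` hidden columns)."""
    text = Path(path).read_text()
    meta = _parse_meta(text)
    trials = pd.read_csv(io.StringIO(text), comment="#",
                         float_precision="round_trip")
    for col in ("rotation_deg", "theta_hand_deg", "theta_noisy_deg"):
        if col in trials.columns:
            trials[col] = trials[col].astype(float)
    required = {"trial", "phase", "rotation_deg", "theta_hand_deg",
                "theta_noisy_deg", "rewarded"}
    missing = required - set(trials.columns)
    if missing:
        raise DataError(f"session file missing columns: {sorted(missing)}")

    def _float(key: str, default: float) -> float:
        raw = meta.get(key)
        return default if raw in (None, "none") else float(raw)

    clamp_raw = meta.get("clamp_ceiling", "none")
    protocol = TaskProtocol(
        blocks=_blocks_from_trials(trials),
        baseline_zone_halfwidth=_float("baseline_zone_halfwidth", 5.75),
        running_mean_window=int(_float("running_mean_window", 10)),
        noise_multiplier=_float("noise_multiplier", 1.0),
        clamp_ceiling=None if clamp_raw == "none" else float(clamp_raw),
        rotation_sign_order=int(_float("rotation_sign_order", -1)),
    )
    seed_raw = meta.get("rng_seed", "none")
    return Session(
        protocol=protocol,
        trials=trials,
        sigma_bl=_float("sigma_bl", 0.0),
        rng_seed=None if seed_raw == "none" else int(seed_raw),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def protocol_from_mapping(cfg: Mapping[str, Any]) -> TaskProtocol:
    """Build a protocol from a config mapping.

    Either supply ``blocks`` (list of ``{phase, n_trials, rotation}``) or
    omit it to get the standard 420-trial schedule; scalar fields override
    the defaults.
    """
    kwargs: dict[str, Any] = {}
    for key in (
        "baseline_zone_halfwidth", "running_mean_window", "noise_multiplier",
        "clamp_ceiling", "rotation_sign_order",
    ):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "blocks" in cfg:
        blocks = tuple(
            Block(str(b["phase"]), int(b["n_trials"]), float(b.get("rotation", 0.0)))
            for b in cfg["blocks"]
        )
        return TaskProtocol(blocks=blocks, **kwargs)
    alpha = kwargs.pop("noise_multiplier", 1.0)
    sign = kwargs.pop("rotation_sign_order", -1)
    clamp = kwargs.pop("clamp_ceiling", None)
    return TaskProtocol.experiment1(
        alpha=alpha, rotation_sign_order=sign, clamp_ceiling=clamp, **kwargs
    )


def agent_from_mapping(cfg: Mapping[str, Any]) -> AgentParams:
    try:
        return AgentParams(
            sigma_m=float(cfg["sigma_m"]),
            sigma_e_rewarded=float(cfg["sigma_e_rewarded"]),
            sigma_e_unrewarded=float(cfg["sigma_e_unrewarded"]),
            x0=float(cfg.get("x0", 0.0)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"agent config missing field {exc}") from None


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config file into a plain mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return cfg
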