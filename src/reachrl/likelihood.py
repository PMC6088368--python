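"""Particle-filter likelihood for the reward-gated random-walk reach model.

The observation model for the executed reach angle on trial t is
``y_t = x_t + e_t + m_t`` with exploration ``e_t ~ N(0, sigma_e^2)`` (SD
conditional on the previous trial's reward) and motor noise
``m_t ~ N(0, sigma_m^2)``.  The latent estimate updates ``x_{t+1} = x_t + e_t``
after rewarded trials and is otherwise unchanged.  Because the agent credits
only the exploration component, the filtered state is non-Gaussian in general
and the likelihood is estimated by sequential Monte Carlo:

1. weight each particle by ``N(y_t; x_t^r, sigma_m^2 + sigma_e^2)``,
2. the per-trial likelihood is the mean weight,
3. normalize weights,
4. resample R particles (multinomial by default),
5. propagate: after a rewarded trial, draw ``e_t^r`` from its exact Gaussian
   conditional given ``y_t`` and ``x_t^r`` — mean ``rho * (y_t - x_t^r)``,
   variance ``rho * sigma_m^2`` with ``rho = sigma_e^2 / (sigma_e^2 +
   sigma_m^2)`` — and set ``x_{t+1}^r = x_t^r + e_t^r``.

With ``sigma_m = 0`` the model is degenerate-Gaussian and
:func:`closed_form_loglik` gives the exact answer (the recursion
``x_{t+1} = y_t`` after reward), which serves as an independent oracle for
the filter.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ContractError, DataError, DegenerateModelError, OraclePreconditionError
from .task import AgentParams, Session

__all__ = [
    "ParticleEnsemble",
    "LikelihoodEstimate",
    "pf_loglik",
    "closed_form_loglik",
    "ess_diagnostic",
    "LOG_DENSITY_FLOOR",
]

logger = logging.getLogger(__name__)

#: Floor applied to a per-trial log-likelihood term when every particle
#: weight underflows; keeps the objective finite on absurd proposals.
LOG_DENSITY_FLOOR = -745.0

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class ParticleEnsemble:
    """Snapshot of the particle system at one trial."""

    estimates: np.ndarray           # latent-state value per particle, deg
    weights: np.ndarray             # unnormalized observation weights
    normalized_weights: np.ndarray  # weights rescaled to sum to 1
    t: int                          # trial index (1-based)

    @property
    def R(self) -> int:
        return len(self.estimates)


def ess_diagnostic(ensemble: ParticleEnsemble) -> float:
    """Effective sample size ``1 / sum(w_hat^2)``, in ``[1, R]``."""
    w = np.asarray(ensemble.normalized_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ContractError("normalized weights must sum to 1")
    return float(1.0 / np.sum(w * w))


@dataclass
class LikelihoodEstimate:
    """Particle-filter output: total and per-trial log-likelihood terms."""

    log_likelihood: float
    per_trial_log_lik: np.ndarray
    R: int
    seed: int
    effective_sample_size_min: float


def _session_arrays(session: Session) -> tuple[np.ndarray, np.ndarray]:
    y = session.trials["theta_hand_deg"].to_numpy(dtype=float)
    rewarded = session.trials["rewarded"].to_numpy(dtype=bool)
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite reach angle in session")
    return y, rewarded


def _initial_estimate(session: Session, x0: float | None) -> float:
    if x0 is not None:
        return float(x0)
    bl1 = session.phase_frame("BL1")
    if len(bl1) == 0:
        raise DataError("session has no BL1 phase; pass x0 explicitly")
    return float(bl1["theta_hand_deg"].mean())


def _context_variances(params: AgentParams) -> tuple[float, float]:
    """(rewarded-context, unrewarded-context) observation variances."""
    vm = params.sigma_m ** 2
    v_r = vm + params.sigma_e_rewarded ** 2
    v_u = vm + params.sigma_e_unrewarded ** 2
    if v_r <= 0 or v_u <= 0:
        raise DegenerateModelError(
            "sigma_m^2 + sigma_e^2 must be > 0 in every reward context"
        )
    return v_r, v_u


@njit(cache=True, fastmath=True)
def _pf_core(
    y, rewarded, x_init, v_r, v_u, sigma_m2, R, seed,
    sample_propagation, systematic, floor,
):  # pragma: no cover - exercised through pf_loglik
    np.random.seed(seed)
    T = y.shape[0]
    x = np.full(R, x_init)
    xn = np.empty(R)
    logw = np.empty(R)
    cs = np.empty(R)
    per_trial = np.empty(T)
    ess_min = float(R)
    prev_rewarded = True
    underflow = 0
    log_2pi = math.log(2.0 * math.pi)
    for t in range(T):
        var = v_r if prev_rewarded else v_u
        const = -0.5 * (log_2pi + math.log(var))
        inv2v = 1.0 / (2.0 * var)
        shift = -np.inf
        for i in range(R):
            d = y[t] - x[i]
            lw = const - d * d * inv2v
            logw[i] = lw
            if lw > shift:
                shift = lw
        if not np.isfinite(shift):
            # every particle underflowed: floor this trial, keep states
            per_trial[t] = floor
            underflow += 1
            prev_rewarded = rewarded[t]
            continue
        total = 0.0
        sumsq = 0.0
        for i in range(R):
            wi = math.exp(logw[i] - shift)
            total += wi
            sumsq += wi * wi
            cs[i] = total
        per_trial[t] = shift + math.log(total) - math.log(R)
        ess = total * total / sumsq
        if ess < ess_min:
            ess_min = ess

        # Resample by one merge pass of an increasing uniform grid against
        # the cumulative weights.  For the multinomial scheme the grid is
        # the order statistics of R uniforms, generated via cumulative
        # exponential spacings (reusing the logw buffer); for the
        # systematic scheme it is the usual stratified comb.
        if systematic:
            u0 = np.random.random()
            scale = total / R
            for i in range(R):
                logw[i] = (u0 + i) * scale
        else:  # multinomial, every trial
            acc = 0.0
            for i in range(R):
                acc -= math.log(1.0 - np.random.random())
                logw[i] = acc
            acc -= math.log(1.0 - np.random.random())
            scale = total / acc
            for i in range(R):
                logw[i] *= scale
        j = 0
        for i in range(R):
            u = logw[i]
            while cs[j] < u and j < R - 1:
                j += 1
            xn[i] = x[j]
        x, xn = xn, x

        # propagate: credit the conditional exploration component
        if rewarded[t]:
            sigma_e2 = var - sigma_m2
            rho = sigma_e2 / var
            sd = math.sqrt(rho * sigma_m2)
            if sample_propagation and sd > 0.0:
                for i in range(R):
                    e = rho * (y[t] - x[i]) + sd * np.random.standard_normal()
                    x[i] += e
            else:
                for i in range(R):
                    x[i] += rho * (y[t] - x[i])
        prev_rewarded = rewarded[t]
    return per_trial, ess_min, underflow


def pf_loglik(
    session: Session,
    params: AgentParams,
    variant=None,
    R: int = 10_000,
    seed: int = 0,
    *,
    x0: float | None = None,
    resampling: str = "multinomial",
    propagation: str = "sampled",
) -> LikelihoodEstimate:
    """Sequential-Monte-Carlo estimate of the session log-likelihood.

    All particles start at the BL1 mean reach angle (or ``x0``).  The trial-t
    exploration context is set by the reward on trial t-1; the first trial
    uses the rewarded context.  The estimate is deterministic given ``seed``.

    Parameters
    ----------
    variant
        Optional :class:`~reachrl.fitting.ModelVariant`; when given, ``params``
        must satisfy its tying rules.
    resampling
        ``"multinomial"`` (every trial) or ``"systematic"``.
    propagation
        ``"sampled"`` draws e from its conditional law after reward;
        ``"mean"`` applies only the conditional mean (sensitivity option).
    """
    if R < 2:
        raise ContractError("R must be >= 2")
    if resampling not in ("multinomial", "systematic"):
        raise ContractError(f"unknown resampling scheme {resampling!r}")
    if propagation not in ("sampled", "mean"):
        raise ContractError(f"unknown propagation scheme {propagation!r}")
    if variant is not None:
        variant.validate_params(params)

    y, rewarded = _session_arrays(session)
    v_r, v_u = _context_variances(params)

    per_trial, ess_min, underflow = _pf_core(
        y,
        rewarded,
        float(_initial_estimate(session, x0)),
        v_r,
        v_u,
        params.sigma_m ** 2,
        int(R),
        int(seed) & 0x7FFFFFFF,
        propagation == "sampled",
        resampling == "systematic",
        LOG_DENSITY_FLOOR,
    )
    T = len(y)

    if underflow:
        logger.warning(
            "pf_loglik: %d/%d trials hit the log-density floor (%g)",
            underflow, T, LOG_DENSITY_FLOOR,
        )
    return LikelihoodEstimate(
        log_likelihood=float(per_trial.sum()),
        per_trial_log_lik=per_trial,
        R=R,
        seed=int(seed),
        effective_sample_size_min=ess_min,
    )


def closed_form_loglik(
    session: Session, params: AgentParams, *, x0: float | None = None
) -> float:
    """Exact log-likelihood for the motor-noise-free model (``sigma_m = 0``).

    Without motor noise a rewarded trial reveals the exploration draw
    exactly, so the latent estimate is known: ``x_{t+1} = y_t`` after reward,
    unchanged otherwise.  The likelihood is then a product of Gaussian
    densities with the reward-context exploration variance.
    """
    if params.sigma_m != 0:
        raise OraclePreconditionError("closed-form oracle requires sigma_m = 0")
    if params.sigma_e_rewarded <= 0 or params.sigma_e_unrewarded <= 0:
        raise DegenerateModelError("sigma_e must be > 0 in both reward contexts")

    y, rewarded = _session_arrays(session)
    T = len(y)
    xs = np.empty(T)
    x = _initial_estimate(session, x0)
    for t in range(T):
        xs[t] = x
        if rewarded[t]:
            x = y[t]
    # context of trial t = reward on trial t-1 (first trial: rewarded)
    ctx_rewarded = np.concatenate(([True], rewarded[:-1]))
    resid2 = (y - xs) ** 2
    ll = 0.0
    for mask, sigma in (
        (ctx_rewarded, params.sigma_e_rewarded),
        (~ctx_rewarded, params.sigma_e_unrewarded),
    ):
        n = int(mask.sum())
        if n:
            var = sigma * sigma
            ll += -0.5 * n * (_LOG_2PI + math.log(var)) - resid2[mask].sum() / (2 * var)
    return float(ll)
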