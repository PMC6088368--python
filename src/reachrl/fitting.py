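"""Maximum-likelihood fitting of the reach model and summed-BIC comparison.

Three nested variants are fit per session:

* ``three_param`` — sigma_m, sigma_e_rewarded, sigma_e_unrewarded;
* ``two_param``  — exploration independent of reward history
  (sigma_e_rewarded = sigma_e_unrewarded);
* ``one_param``  — no motor noise (sigma_m = 0), single sigma_e; fit with
  the exact closed-form likelihood.

The particle-filter objective is made deterministic by fixing the filter
seed across all evaluations (common random numbers), so a standard bounded
derivative-free optimizer (Nelder-Mead with multi-start) applies.  Model
comparison sums degrees of freedom, trial counts, and log-likelihoods over
sessions before computing BIC = k*ln(n) - 2*LL, and reports each variant's
BIC difference from the best (0 for the winner).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, ContractError
from .likelihood import closed_form_loglik, pf_loglik
from .task import AgentParams, Session

__all__ = [
    "ModelVariant",
    "THREE_PARAM",
    "TWO_PARAM",
    "ONE_PARAM",
    "VARIANTS",
    "get_variant",
    "FitResult",
    "ModelComparison",
    "fit_mle",
    "bic_total",
    "compare_models",
]


@dataclass(frozen=True)
class ModelVariant:
    """A named model variant with its free parameters and tying rules."""

    name: str
    free_parameters: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.free_parameters)

    def build_params(self, theta: Sequence[float], x0: float = 0.0) -> AgentParams:
        """Map a free-parameter vector to a full :class:`AgentParams`."""
        theta = tuple(float(v) for v in theta)
        if len(theta) != self.k:
            raise ContractError(f"{self.name} expects {self.k} parameters")
        if self.name == "three_param":
            return AgentParams(theta[0], theta[1], theta[2], x0)
        if self.name == "two_param":
            return AgentParams(theta[0], theta[1], theta[1], x0)
        if self.name == "one_param":
            return AgentParams(0.0, theta[0], theta[0], x0)
        raise ContractError(f"unknown variant {self.name!r}")

    def validate_params(self, params: AgentParams) -> None:
        """Check that ``params`` satisfies this variant's tying rules."""
        if self.name == "two_param" and (
            params.sigma_e_rewarded != params.sigma_e_unrewarded
        ):
            raise ContractError("two_param ties the two exploration SDs")
        if self.name == "one_param" and (
            params.sigma_m != 0
            or params.sigma_e_rewarded != params.sigma_e_unrewarded
        ):
            raise ContractError("one_param fixes sigma_m = 0 and ties sigma_e")


THREE_PARAM = ModelVariant(
    "three_param", ("sigma_m", "sigma_e_rewarded", "sigma_e_unrewarded")
)
TWO_PARAM = ModelVariant("two_param", ("sigma_m", "sigma_e"))
ONE_PARAM = ModelVariant("one_param", ("sigma_e",))

VARIANTS: dict[str, ModelVariant] = {
    v.name: v for v in (THREE_PARAM, TWO_PARAM, ONE_PARAM)
}


def get_variant(name: str) -> ModelVariant:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
        ) from None


@dataclass
class FitResult:
    """One session's maximum-likelihood fit under one variant."""

    variant: ModelVariant
    params_hat: AgentParams
    log_likelihood: float
    n_trials: int
    k: int
    seed: int
    optimizer_trace: list[tuple[tuple[float, ...], float]] = field(repr=False)
    converged: bool = True


def fit_mle(
    session: Session,
    variant: ModelVariant,
    R: int = 2000,
    seed: int = 0,
    bounds: tuple[float, float] = (0.01, 20.0),
    *,
    start_fractions: Sequence[float] = (0.25, 0.5, 0.75),
    maxfev: int = 300,
    xatol: float = 0.02,
    fatol: float = 0.5,
    x0: float | None = None,
) -> FitResult:
    """Bounded derivative-free MLE of a variant's parameters on one session.

    The objective is the particle-filter log-likelihood evaluated with a
    fixed seed (common random numbers), so repeated evaluations at the same
    parameters return the same value and the whole fit is reproducible
    bit-for-bit.  ``one_param`` uses the exact closed-form likelihood.
    Multi-start: each entry of ``start_fractions`` seeds all SDs at that
    fraction of the session's overall reach-angle SD; the best final value
    is retained.  Non-convergence within the budget is flagged on the
    result, never raised.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not (0 < lo < hi) or not math.isfinite(hi):
        raise ConfigurationError("bounds must be finite with 0 < lo < hi")

    trace: list[tuple[tuple[float, ...], float]] = []

    def objective(theta: np.ndarray) -> float:
        theta = np.clip(theta, lo, hi)
        params = variant.build_params(theta)
        if variant.name == "one_param":
            ll = closed_form_loglik(session, params, x0=x0)
        else:
            ll = pf_loglik(session, params, R=R, seed=seed, x0=x0).log_likelihood
        trace.append((tuple(float(v) for v in theta), float(ll)))
        return -ll

    overall_sd = float(np.std(session.trials["theta_hand_deg"].to_numpy(), ddof=1))
    if not math.isfinite(overall_sd) or overall_sd <= 0:
        overall_sd = 1.0

    best = None
    any_success = False
    for frac in start_fractions:
        theta0 = np.clip(np.full(variant.k, frac * overall_sd), lo, hi)
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            bounds=[(lo, hi)] * variant.k,
            options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = np.clip(best.x, lo, hi)
    params_hat = variant.build_params(theta_hat)
    return FitResult(
        variant=variant,
        params_hat=params_hat,
        log_likelihood=float(-best.fun),
        n_trials=session.n_trials,
        k=variant.k,
        seed=int(seed),
        optimizer_trace=trace,
        converged=any_success,
    )


def bic_total(sum_ll: float, sum_k: int, sum_n: int) -> float:
    """Summed Bayesian information criterion: ``k * ln(n) - 2 * LL`` with
    degrees of freedom, trial counts, and log-likelihoods already summed
    across sessions."""
    if sum_n < 1:
        raise ContractError("sum_n must be >= 1")
    return float(sum_k * math.log(sum_n) - 2.0 * sum_ll)


@dataclass
class ModelComparison:
    """Across-session BIC comparison of model variants."""

    totals: dict[str, dict[str, float]]  # per variant: sum_ll, sum_k, sum_n, bic, delta_bic
    best_variant: str

    def to_frame(self):
        import pandas as pd

        rows = [
            {"variant": name, **vals} for name, vals in self.totals.items()
        ]
        return pd.DataFrame(rows)


def compare_models(
    fits_by_variant: Mapping[str, Sequence[FitResult]]
) -> ModelComparison:
    """Summed-BIC comparison across sessions; best variant has delta BIC 0.

    Every variant must carry a fit for every session (balanced sets).
    """
    if not fits_by_variant:
        raise ContractError("no fits supplied")
    counts = {name: len(fits) for name, fits in fits_by_variant.items()}
    if len(set(counts.values())) != 1 or min(counts.values()) == 0:
        raise ContractError(f"unbalanced fit sets: {counts}")
    n_lists = {
        name: sorted(f.n_trials for f in fits)
        for name, fits in fits_by_variant.items()
    }
    if len({tuple(v) for v in n_lists.values()}) != 1:
        raise ContractError("fit sets cover different sessions (trial counts differ)")

    totals: dict[str, dict[str, float]] = {}
    for name, fits in fits_by_variant.items():
        sum_ll = float(sum(f.log_likelihood for f in fits))
        sum_k = int(sum(f.k for f in fits))
        sum_n = int(sum(f.n_trials for f in fits))
        totals[name] = {
            "sum_ll": sum_ll,
            "sum_k": sum_k,
            "sum_n": sum_n,
            "bic": bic_total(sum_ll, sum_k, sum_n),
        }
    best = min(totals, key=lambda name: totals[name]["bic"])
    best_bic = totals[best]["bic"]
    for vals in totals.values():
        vals["delta_bic"] = vals["bic"] - best_bic
    return ModelComparison(totals=totals, best_variant=best)
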