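"""Bayesian-decision-theoretic model of approach latency under threat.

An agent decides *when* to approach a reward that decays over time while an
exposure to threat may punish the movement.  Expected utility of approaching
at latency ``t1`` and staying exposed for ``delta_t`` is

    Z(t1, delta_t) = P_L(t1, delta_t) * L  +  P_G(t1) * G  [- motor cost]

with gain utility ``G > 0``, loss utility ``L < 0``, gain survival prior
``P_G(t1) = exp(-lambda1 * t1)`` and a threat prior ``P_L``.  Two regimes are
distinguished:

* **objective task statistics** — the threat is a homogeneous Poisson hazard
  during exposure only, so ``P_L = 1 - exp(-lambda2 * delta_t)`` does not
  depend on ``t1`` and the optimal move is as early as possible (boundary
  maximiser);
* **correlated-environment prior** — the agent believes threat probability is
  high right after a reward appears and decays afterwards; when the threat
  prior decays faster than the gain prior, an interior optimal latency exists
  and it shifts later when loss magnitude or loss probability grow.

All times are seconds; utilities are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "UtilityParams",
    "GainPrior",
    "PoissonThreat",
    "ThreatPrior",
    "MotorCost",
    "DecisionModel",
    "OptimalLatency",
    "AssumptionReport",
    "ScalingError",
    "quadratic_threat_prior",
    "gain_probability",
    "exposure_loss_probability",
    "rate_from_catch_probability",
    "expected_utility",
    "utility_derivative",
    "optimal_latency",
    "verify_assumptions",
    "latency_shift_under_scaling",
]


class ScalingError(ValueError):
    """Scaling a threat prior pushed probability above 1 inside the search interval."""


@dataclass(frozen=True)
class UtilityParams:
    """Utilities of the two outcomes: ``gain > 0`` per collected reward, ``loss < 0``."""

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain utility must be > 0, got {self.gain}")
        if not self.loss < 0:
            raise ValueError(f"loss utility must be < 0, got {self.loss}")


@dataclass(frozen=True)
class GainPrior:
    """Reward availability decays exponentially: P_G(t1) = exp(-rate * t1)."""

    rate: float  # reward-disappearance rate, 1/s

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"disappearance rate must be > 0, got {self.rate}")

    def value(self, t1):
        t1 = np.asarray(t1, dtype=float)
        if np.any(t1 < 0):
            raise ValueError("approach latency must be non-negative")
        return np.exp(-self.rate * t1)

    def d1(self, t1):
        return -self.rate * self.value(t1)

    def d2(self, t1):
        return self.rate**2 * self.value(t1)


@dataclass(frozen=True)
class PoissonThreat:
    """Homogeneous Poisson threat: activation hazard runs only during exposure.

    Loss probability depends on the exposure duration alone, never on the
    approach latency, so it contributes nothing to the latency optimisation.
    """

    rate: float  # activation rate lambda2, 1/s

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"threat activation rate must be > 0, got {self.rate}")

    def loss_probability(self, delta_t):
        delta_t = np.asarray(delta_t, dtype=float)
        if np.any(delta_t < 0):
            raise ValueError("exposure duration must be non-negative")
        return 1.0 - np.exp(-self.rate * delta_t)


@dataclass(frozen=True)
class ThreatPrior:
    """Subjective time-dependent threat probability with derivative contracts.

    ``value`` maps approach latency to a probability in [0, 1] on ``support``;
    ``d1`` and ``d2`` are its first and second derivatives.  All three must
    accept numpy arrays.
    """

    value: Callable[[np.ndarray], np.ndarray]
    d1: Callable[[np.ndarray], np.ndarray]
    d2: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float] = (0.0, 5.0)

    def check_domain(self, t1) -> None:
        lo, hi = self.support
        t1 = np.asarray(t1, dtype=float)
        if np.any(t1 < lo) or np.any(t1 > hi):
            raise ValueError(f"latency outside prior support [{lo}, {hi}]")


def quadratic_threat_prior(
    baseline: float,
    deriv_intercept: float,
    deriv_slope: float,
    support: tuple[float, float] = (0.0, 5.0),
) -> ThreatPrior:
    """Clamped-quadratic threat prior: derivative min(a0 + a1*t, 0), integrated.

    With ``a0 = deriv_intercept < 0`` and ``a1 = deriv_slope > 0`` the
    derivative rises linearly to zero at ``t_c = -a0/a1`` and the prior is
    constant beyond that point — threat high right after the reward appears,
    decaying to a floor.  ``baseline`` is the prior value at t = 0.  Values
    are clipped to [0, 1].
    """
    a0, a1 = float(deriv_intercept), float(deriv_slope)
    if a1 > 0 and a0 < 0:
        t_clamp = -a0 / a1
    elif a0 >= 0:
        t_clamp = 0.0  # derivative clamped everywhere: constant prior
    else:
        t_clamp = math.inf  # derivative negative on all of support

    def raw(t):
        t = np.asarray(t, dtype=float)
        tc = np.minimum(t, t_clamp)
        return baseline + a0 * tc + 0.5 * a1 * tc**2

    def value(t):
        return np.clip(raw(t), 0.0, 1.0)

    def d1(t):
        t = np.asarray(t, dtype=float)
        inside = (raw(t) > 0.0) & (raw(t) < 1.0) & (t < t_clamp)
        return np.where(inside, np.minimum(a0 + a1 * t, 0.0), 0.0)

    def d2(t):
        t = np.asarray(t, dtype=float)
        inside = (raw(t) > 0.0) & (raw(t) < 1.0) & (t < t_clamp)
        return np.where(inside, a1, 0.0)

    return ThreatPrior(value=value, d1=d1, d2=d2, support=support)


@dataclass(frozen=True)
class MotorCost:
    """Additive time-dependent movement cost c(t1) = c0 * exp(-decay * t1).

    A cost that is large for very fast movements and relaxes over time can by
    itself produce a non-zero optimal latency even under the objective task
    statistics — but that optimum depends only on the gain side, not on loss
    magnitude or probability, which is what distinguishes it empirically from
    a threat prior.
    """

    c0: float
    decay: float

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.decay < 0:
            raise ValueError("motor cost parameters must be non-negative")

    def value(self, t1):
        return self.c0 * np.exp(-self.decay * np.asarray(t1, dtype=float))

    def d1(self, t1):
        return -self.decay * self.value(t1)


@dataclass(frozen=True)
class DecisionModel:
    """Everything needed to evaluate expected utility of a timed approach.

    ``threat`` is either a :class:`PoissonThreat` (objective statistics) or a
    :class:`ThreatPrior` (subjective correlated-environment prior).  For a
    ThreatPrior the loss probability is treated as separable,
    ``P_L(t1, dt) = threat_scale * prior(t1)``, with the exposure-dependent
    factor absorbed into ``threat_scale``; only the t1-dependence enters the
    optimisation, consistent with the exposure duration being planned
    independently of the approach latency.
    """

    utilities: UtilityParams
    gain_prior: GainPrior
    threat: Union[PoissonThreat, ThreatPrior]
    delta_t: float = 0.1  # planned exposure duration, independent of t1
    threat_scale: float = 1.0
    motor_cost: Optional[MotorCost] = None

    def __post_init__(self) -> None:
        if not self.delta_t >= 0:
            raise ValueError("exposure duration must be non-negative")
        if not self.threat_scale > 0:
            raise ValueError("threat scale must be > 0")

    @property
    def has_prior(self) -> bool:
        return isinstance(self.threat, ThreatPrior)

    def loss_probability(self, t1):
        """P_L as a function of approach latency (constant for Poisson threat)."""
        if self.has_prior:
            self.threat.check_domain(t1)
            return self.threat_scale * self.threat.value(t1)
        p = self.threat.loss_probability(self.delta_t) * self.threat_scale
        return np.full_like(np.asarray(t1, dtype=float), float(p))


def gain_probability(t1, prior: GainPrior):
    """Probability the reward is still available at approach latency ``t1``."""
    return prior.value(t1)


def exposure_loss_probability(delta_t, threat: PoissonThreat):
    """Probability of at least one threat activation during ``delta_t`` of exposure."""
    return threat.loss_probability(delta_t)


def rate_from_catch_probability(p: float, delta_t: float) -> float:
    """Poisson activation rate producing catch probability ``p`` over ``delta_t``.

    Inverse of :func:`exposure_loss_probability`:  lambda2 = -ln(1 - p) / delta_t.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"catch probability must be in (0, 1), got {p}")
    if not delta_t > 0:
        raise ValueError(f"exposure duration must be > 0, got {delta_t}")
    return -math.log1p(-p) / delta_t


def expected_utility(t1, model: DecisionModel):
    """Expected utility Z(t1) = P_L * L + P_G * G, minus any motor cost."""
    t1_arr = np.asarray(t1, dtype=float)
    z = model.loss_probability(t1_arr) * model.utilities.loss + gain_probability(
        t1_arr, model.gain_prior
    ) * model.utilities.gain
    if model.motor_cost is not None:
        z = z - model.motor_cost.value(t1_arr)
    return z if np.ndim(t1) else float(z)


def utility_derivative(t1, model: DecisionModel):
    """dZ/dt1 from the priors' analytic derivatives.

    Exposure duration is planned independently of the approach latency, so for
    the Poisson threat the loss term has zero derivative and
    dZ/dt1 = -G * lambda1 * exp(-lambda1 * t1) (strictly negative).
    """
    t1_arr = np.asarray(t1, dtype=float)
    dz = model.utilities.gain * model.gain_prior.d1(t1_arr)
    if model.has_prior:
        model.threat.check_domain(t1_arr)
        dz = dz + model.utilities.loss * model.threat_scale * model.threat.d1(t1_arr)
    if model.motor_cost is not None:
        dz = dz - model.motor_cost.d1(t1_arr)
    return dz if np.ndim(t1) else float(dz)


@dataclass(frozen=True)
class OptimalLatency:
    """Result of the latency optimisation."""

    t1: float
    utility: float
    boundary: bool  # True when the maximiser sits on an interval endpoint


def optimal_latency(
    model: DecisionModel,
    interval: tuple[float, float] = (0.0, 5.0),
    resolution: float = 1e-3,
) -> OptimalLatency:
    """Global maximiser of expected utility over ``interval``.

    Dense grid scan at ``resolution``, then bisection refinement of the
    derivative's sign change around the best grid point.  Among ties the
    smaller latency wins (argmax returns the first maximum).  Boundary
    maximisers are returned flagged rather than raising; for the Poisson
    threat without motor cost this is always the left endpoint.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not hi > lo or lo < 0:
        raise ValueError("interval must satisfy 0 <= lo < hi")
    if not resolution > 0:
        raise ValueError("resolution must be > 0")

    grid = np.arange(lo, hi + 0.5 * resolution, resolution)
    grid[-1] = hi
    z = np.asarray(expected_utility(grid, model), dtype=float)
    i = int(np.argmax(z))

    if i == 0 or i == len(grid) - 1:
        return OptimalLatency(t1=float(grid[i]), utility=float(z[i]), boundary=True)

    # refine: the derivative changes sign + -> - inside [grid[i-1], grid[i+1]]
    a, b = float(grid[i - 1]), float(grid[i + 1])
    fa = float(utility_derivative(a, model))
    fb = float(utility_derivative(b, model))
    t_star = float(grid[i])
    if fa > 0 > fb:
        t_star = float(brentq(lambda t: float(utility_derivative(t, model)), a, b))
    elif fa > 0 and float(utility_derivative(t_star, model)) < 0:
        t_star = float(brentq(lambda t: float(utility_derivative(t, model)), a, t_star))
    elif fb < 0 and float(utility_derivative(t_star, model)) > 0:
        t_star = float(brentq(lambda t: float(utility_derivative(t, model)), t_star, b))
    return OptimalLatency(
        t1=t_star, utility=float(expected_utility(t_star, model)), boundary=False
    )


@dataclass(frozen=True)
class AssumptionReport:
    """Checks of the correlated-environment conditions that guarantee an interior optimum.

    ``threat_decreasing``: the threat prior decays everywhere on the interval.
    ``gain_decreasing``: expected gain decays everywhere on the interval.
    ``derivative_crossing``: dZ/dt1 is positive at the left end and negative at
    the right end, so a stationary point with a + to - sign change (a local
    maximiser) exists inside.
    """

    threat_decreasing: bool
    gain_decreasing: bool
    derivative_crossing: bool

    def all_hold(self) -> bool:
        return self.threat_decreasing and self.gain_decreasing and self.derivative_crossing


def verify_assumptions(
    model: DecisionModel,
    interval: tuple[float, float] = (0.0, 5.0),
    n_grid: int = 512,
) -> AssumptionReport:
    """Evaluate the interior-optimum conditions on a grid over ``interval``."""
    lo, hi = float(interval[0]), float(interval[1])
    grid = np.linspace(lo, hi, n_grid)
    if model.has_prior:
        threat_decreasing = bool(np.all(model.threat.d1(grid) < 0))
    else:
        threat_decreasing = False  # exposure-only threat: dP_L/dt1 = 0
    gain_decreasing = bool(
        np.all(model.utilities.gain * model.gain_prior.d1(grid) < 0)
    )
    f_lo = float(utility_derivative(lo, model))
    f_hi = float(utility_derivative(hi, model))
    crossing = f_lo > 0 > f_hi
    return AssumptionReport(
        threat_decreasing=threat_decreasing,
        gain_decreasing=gain_decreasing,
        derivative_crossing=crossing,
    )


def latency_shift_under_scaling(
    model: DecisionModel,
    k: float,
    mode: str = "loss_magnitude",
    interval: tuple[float, float] = (0.0, 5.0),
    resolution: float = 1e-3,
) -> float:
    """Shift of the optimal latency when loss magnitude or loss probability scales by ``k``.

    ``mode='loss_magnitude'`` replaces L by k*L; ``mode='loss_probability'``
    replaces P_L by min(k*P_L, 1) and raises :class:`ScalingError` if the cap
    would bind inside the searched interval.  For a subjective prior with an
    interior maximiser and small k-1 the shift is non-negative: a larger
    threat delays the approach.  For the objective Poisson threat (with or
    without motor cost) the shift is exactly zero.
    """
    base = optimal_latency(model, interval=interval, resolution=resolution)
    if mode == "loss_magnitude":
        scaled = DecisionModel(
            utilities=UtilityParams(gain=model.utilities.gain, loss=k * model.utilities.loss),
            gain_prior=model.gain_prior,
            threat=model.threat,
            delta_t=model.delta_t,
            threat_scale=model.threat_scale,
            motor_cost=model.motor_cost,
        )
    elif mode == "loss_probability":
        scaled = DecisionModel(
            utilities=model.utilities,
            gain_prior=model.gain_prior,
            threat=model.threat,
            delta_t=model.delta_t,
            threat_scale=k * model.threat_scale,
            motor_cost=model.motor_cost,
        )
        grid = np.arange(interval[0], interval[1], resolution)
        if np.any(scaled.loss_probability(grid) > 1.0 + 1e-12):
            raise ScalingError(
                "scaled loss probability exceeds 1 inside the search interval"
            )
    else:
        raise ValueError(f"unknown scaling mode: {mode!r}")
    new = optimal_latency(scaled, interval=interval, resolution=resolution)
    return new.t1 - base.t1
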