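"""Reconstructing the subjective threat prior from observed approach latencies.

The inversion treats each observed condition-mean latency as a stationary
point of the expected-utility function: at the chosen latency the decaying
expected gain is exactly balanced by the decaying expected loss.  Given an
ideal-observer account of what is at stake on each movement (tokens in hand
plus the foregone expectation of reaching the desired count), the stationarity
condition can be solved for the time derivative of the prior threat
probability at each observed latency.  Those derivative points are fit with a
straight line constrained to be non-positive, integrated to a quadratic prior,
anchored so the prior equals the average catch rate at the average approach
latency, and finally fed forward through the decision model to predict
per-condition approach latencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DecisionModel,
    GainPrior,
    ThreatPrior,
    UtilityParams,
    optimal_latency,
    quadratic_threat_prior,
)

__all__ = [
    "IdealObserverParams",
    "ReconstructedPrior",
    "EstimationError",
    "ConstraintViolationError",
    "estimate_ideal_observer",
    "potential_loss",
    "prior_derivative_points",
    "fit_prior",
    "predict_latencies",
]


class EstimationError(ValueError):
    """Ideal-observer quantities cannot be estimated from the data."""


class ConstraintViolationError(ValueError):
    """The fitted derivative line is positive over the whole latency range."""


@dataclass(frozen=True)
class IdealObserverParams:
    """Per-threat-level quantities entering the opportunity-cost loss.

    ``desired_tokens[i]`` — tokens the player aims to collect at level i
    (mean collected on non-caught epochs, per subject then averaged);
    ``catch_prob[i]`` — empirical probability of getting caught per go
    movement; ``token_prob`` — probability a go movement yields a token when
    not caught; ``scale[i]`` — mean catch rate across levels divided by the
    level-i catch rate, the constant relating the level-i prior to the
    level-average prior.
    """

    desired_tokens: tuple[float, ...]
    catch_prob: tuple[float, ...]
    token_prob: float
    scale: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(d > 0 for d in self.desired_tokens):
            raise ValueError("desired token counts must be > 0")
        if not 0.0 < self.token_prob < 1.0:
            raise ValueError("token probability must be in (0, 1)")
        if not all(0.0 <= p < 1.0 for p in self.catch_prob):
            raise ValueError("catch probabilities must be in [0, 1)")


def estimate_ideal_observer(trials: pd.DataFrame) -> IdealObserverParams:
    """Estimate the ideal observer's inputs from a trial table.

    Desired tokens per level: average number of tokens collected on non-caught
    epochs, per subject and then across subjects.  Catch probability per
    level: catches divided by go movements.  Token probability: tokens
    collected divided by uncaught go movements, pooled.
    """
    levels = sorted(trials["threat_level_index"].unique())
    desired, catch_p = [], []
    epoch_grp = trials.groupby(["subject_id", "epoch_id"])
    epoch_stats = epoch_grp.agg(
        level=("threat_level_index", "first"),
        caught=("caught", "any"),
        collected=("token_collected", "sum"),
    ).reset_index()
    for level in levels:
        lv_trials = trials[trials["threat_level_index"] == level]
        n_go = int(lv_trials["went"].sum())
        if n_go == 0:
            raise EstimationError(f"threat level {level} has no go movements")
        catch_p.append(float(lv_trials["caught"].sum()) / n_go)
        ok = epoch_stats[(epoch_stats["level"] == level) & (~epoch_stats["caught"])]
        if len(ok) == 0:
            raise EstimationError(f"threat level {level} has no non-caught epochs")
        per_subject = ok.groupby("subject_id")["collected"].mean()
        desired.append(float(per_subject.mean()))

    go_ok = trials[trials["went"] & ~trials["caught"]]
    if len(go_ok) == 0:
        raise EstimationError("no uncaught go movements: token probability undefined")
    token_prob = float(go_ok["token_collected"].mean())

    catch = np.asarray(catch_p)
    mean_catch = float(catch.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(catch > 0, mean_catch / catch, np.nan)
    return IdealObserverParams(
        desired_tokens=tuple(desired),
        catch_prob=tuple(catch_p),
        token_prob=min(token_prob, 1.0 - 1e-12),
        scale=tuple(float(s) for s in scale),
    )


def potential_loss(
    level: int,
    tokens_in_hand: int,
    params: IdealObserverParams,
    exponent_includes_token_prob: bool = True,
) -> float:
    """Utility at stake on a movement: tokens in hand plus foregone expectation.

    For ``T`` tokens already collected and desired count ``D_i``, the loss of
    getting caught is the expectation of ending with ``D_i`` tokens, i.e.
    ``-D_i * (1 - P_C)^((D_i - T) / P_T)``: each remaining token requires on
    average ``1/P_T`` exposed movements, each surviving with probability
    ``1 - P_C``.  Once the desired count is reached (``T >= D_i``) the stake is
    simply the ``T`` tokens in hand.  ``exponent_includes_token_prob=False``
    switches to the alternative reading in which ``1/P_T`` multiplies the whole
    expression rather than the exponent.
    """
    if tokens_in_hand < 0:
        raise ValueError("tokens in hand must be >= 0")
    d = params.desired_tokens[level]
    pc = params.catch_prob[level]
    pt = params.token_prob
    t = float(tokens_in_hand)
    if t >= d:
        return -t
    if exponent_includes_token_prob:
        return -d * (1.0 - pc) ** ((d - t) / pt)
    return -d * (1.0 - pc) ** (d - t) / pt


def prior_derivative_points(
    cond_means: pd.DataFrame,
    params: IdealObserverParams,
    gain_prior: GainPrior,
    gain: float = 1.0,
    min_obs: int = 1,
    exponent_includes_token_prob: bool = True,
) -> pd.DataFrame:
    """Solve the stationarity condition for the prior's time derivative.

    For each condition cell with mean latency ``t1``, the derivative of the
    level-average prior is ``-scale_i / L(i, T) * dE(G)/dt1`` evaluated at
    ``t1``, with ``dE(G)/dt1 = -G * lambda1 * exp(-lambda1 * t1)``.  Cells
    flagged missing or with fewer than ``min_obs`` observations are skipped;
    a condition with zero potential loss cannot be inverted and is skipped
    with a warning.
    """
    rows = []
    for _, cell in cond_means.iterrows():
        if bool(cell.get("missing", False)) or int(cell["n_obs"]) < min_obs:
            continue
        t1 = float(cell["mean_approach_latency"])
        if not np.isfinite(t1):
            continue
        level = int(cell["threat_level_index"])
        loss = potential_loss(
            level,
            int(cell["potential_loss"]),
            params,
            exponent_includes_token_prob=exponent_includes_token_prob,
        )
        if loss == 0.0:
            warnings.warn(
                f"condition (level={level}, loss={cell['potential_loss']}) has zero "
                "potential loss; skipped",
                stacklevel=2,
            )
            continue
        d_gain = gain * float(gain_prior.d1(t1))
        rows.append(
            {
                "threat_level_index": level,
                "potential_loss": int(cell["potential_loss"]),
                "t1": t1,
                "derivative": -params.scale[level] / loss * d_gain,
                "n_obs": int(cell["n_obs"]),
            }
        )
    return pd.DataFrame(
        rows, columns=["threat_level_index", "potential_loss", "t1", "derivative", "n_obs"]
    )


@dataclass(frozen=True)
class ReconstructedPrior:
    """Quadratic prior implied by a linear derivative fit plus an anchoring constant.

    The derivative is ``d(t) = min(a0 + a1 * t, 0)`` (non-positive by
    constraint); integrating gives a quadratic that is constant past the clamp
    root, and the anchoring constant places the prior at the average catch
    rate for the average approach latency.
    """

    deriv_intercept: float  # a0
    deriv_slope: float  # a1
    anchor_constant: float  # prior value at t = 0
    anchor_point: tuple[float, float]  # (mean latency, mean catch rate)
    support: tuple[float, float]

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        return np.minimum(self.deriv_intercept + self.deriv_slope * t, 0.0)

    def value(self, t):
        return self.to_threat_prior().value(t)

    def to_threat_prior(self) -> ThreatPrior:
        return quadratic_threat_prior(
            baseline=self.anchor_constant,
            deriv_intercept=self.deriv_intercept,
            deriv_slope=self.deriv_slope,
            support=self.support,
        )


def fit_prior(
    points: pd.DataFrame,
    anchor: tuple[float, float],
    t_max: float = 5.0,
) -> ReconstructedPrior:
    """Fit a line to the derivative points, integrate, and anchor the constant.

    ``anchor`` is (average approach latency, average catch rate): the
    integration constant is chosen so the reconstructed prior passes through
    that point.  Raises :class:`ConstraintViolationError` if the fitted line
    is positive over the whole range of observed latencies (nothing survives
    the non-positivity clamp).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 derivative points to fit a line")
    t = points["t1"].to_numpy(dtype=float)
    d = points["derivative"].to_numpy(dtype=float)
    a1, a0 = np.polyfit(t, d, 1)
    line = a0 + a1 * t
    if np.all(line >= 0):
        raise ConstraintViolationError(
            "fitted derivative line is non-negative over the whole latency range"
        )
    t_anchor, rate_anchor = float(anchor[0]), float(anchor[1])
    # integral of the clamped derivative min(a0 + a1*t, 0) from 0 to t_anchor
    if a1 > 0 and a0 < 0:
        tc = -a0 / a1
        ta = min(t_anchor, tc)
        integral = a0 * ta + 0.5 * a1 * ta**2
    elif a0 >= 0:
        integral = 0.0
    else:
        integral = a0 * t_anchor + 0.5 * a1 * t_anchor**2
    baseline = rate_anchor - integral
    if baseline < 0.0 or baseline > 1.0:
        warnings.warn(
            f"anchoring constant {baseline:.3f} outside [0, 1]; prior values are clipped",
            stacklevel=2,
        )
    return ReconstructedPrior(
        deriv_intercept=float(a0),
        deriv_slope=float(a1),
        anchor_constant=float(baseline),
        anchor_point=(t_anchor, rate_anchor),
        support=(0.0, float(t_max)),
    )


def predict_latencies(
    prior: ReconstructedPrior,
    params: IdealObserverParams,
    gain_prior: GainPrior,
    gain: float = 1.0,
    max_loss: int = 4,
    interval: tuple[float, float] | None = None,
    resolution: float = 1e-3,
    exponent_includes_token_prob: bool = True,
) -> pd.DataFrame:
    """Feed the reconstructed prior forward to per-condition optimal latencies.

    For each (threat level, potential loss) condition, the decision model uses
    the ideal-observer loss and the reconstructed level-average prior scaled
    by 1/scale_i back to the level-specific threat probability.  Conditions
    whose maximiser sits on the interval boundary are flagged non-interior.
    """
    threat = prior.to_threat_prior()
    if interval is None:
        interval = prior.support
    rows = []
    for level in range(len(params.desired_tokens)):
        for loss_tokens in range(0, max_loss + 1):
            loss = potential_loss(
                level, loss_tokens, params,
                exponent_includes_token_prob=exponent_includes_token_prob,
            )
            if loss >= 0.0:
                rows.append(
                    {
                        "threat_level_index": level,
                        "potential_loss": loss_tokens,
                        "predicted_latency": interval[0],
                        "interior": False,
                        "loss_utility": loss,
                    }
                )
                continue
            dm = DecisionModel(
                utilities=UtilityParams(gain=gain, loss=loss),
                gain_prior=gain_prior,
                threat=threat,
                threat_scale=1.0 / params.scale[level],
            )
            opt = optimal_latency(dm, interval=interval, resolution=resolution)
            rows.append(
                {
                    "threat_level_index": level,
                    "potential_loss": loss_tokens,
                    "predicted_latency": opt.t1,
                    "interior": not opt.boundary,
                    "loss_utility": loss,
                }
            )
    return pd.DataFrame(rows)
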