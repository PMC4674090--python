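"""Operant-conflict game simulator.

Emulates a token-foraging game played against a dormant "predator": on each
epoch up to six reward tokens appear sequentially; the player may leave a safe
place to collect each one.  While the player is outside the safe place the
predator can wake in any 20 ms time bin with a constant hazard; waking removes
every token collected so far and ends the epoch.  Token lifetimes and the
variable part of inter-token intervals are exponential with mean 1.25 s, and
the three predator hazards are tailored so that 100 ms of exposure is caught
with probability 0.1, 0.2 or 0.3.

Agent behaviour is pluggable through :class:`AgentPolicy`; the
decision-theoretic agent built by :func:`make_bdt_agent` plans its approach
latency by maximising expected utility under a subjective threat prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DecisionModel,
    GainPrior,
    OptimalLatency,
    ThreatPrior,
    UtilityParams,
    optimal_latency,
    rate_from_catch_probability,
)

__all__ = [
    "TaskConfig",
    "AgentPolicy",
    "TRIAL_COLUMNS",
    "draw_exposure_catch",
    "simulate_epoch",
    "simulate_experiment",
    "make_bdt_agent",
    "make_fixed_agent",
    "make_never_go_agent",
    "make_random_agent",
]

#: Column order of the tidy trial table produced by the simulator.
TRIAL_COLUMNS = [
    "subject_id",
    "epoch_id",
    "token_index",
    "threat_level_index",
    "potential_loss",
    "went",
    "approach_latency",
    "return_latency",
    "correct_direction",
    "token_collected",
    "caught",
]


@dataclass(frozen=True)
class TaskConfig:
    """Game parameters.

    ``threat_levels`` are per-100 ms catch probabilities; the corresponding
    Poisson activation rates follow as -ln(1-p)/0.1 s.  ``activation_bin`` is
    the 20 ms discretisation of the predator's wake-up process.
    """

    n_epochs: int = 270
    tokens_per_epoch: int = 6
    token_lifetime_mean: float = 1.25
    iti_constant: float = 0.5
    iti_variable_mean: float = 1.25
    threat_levels: tuple[float, ...] = (0.1, 0.2, 0.3)
    threat_reference_exposure: float = 0.1
    activation_bin: float = 0.02
    approach_window: tuple[float, float] = (0.150, 2.000)
    return_window: tuple[float, float] = (0.0, 2.000)

    def __post_init__(self) -> None:
        for name in ("token_lifetime_mean", "iti_constant", "iti_variable_mean",
                     "activation_bin", "threat_reference_exposure"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_epochs < 1 or self.tokens_per_epoch < 1:
            raise ValueError("epoch and token counts must be >= 1")
        levels = tuple(self.threat_levels)
        if not all(0.0 < p < 1.0 for p in levels):
            raise ValueError("threat levels must be probabilities in (0, 1)")
        if list(levels) != sorted(levels):
            raise ValueError("threat levels must be sorted ascending")
        object.__setattr__(self, "threat_levels", levels)

    @property
    def threat_rates(self) -> tuple[float, ...]:
        """Poisson activation rate per threat level (1/s)."""
        return tuple(
            rate_from_catch_probability(p, self.threat_reference_exposure)
            for p in self.threat_levels
        )


@dataclass
class AgentPolicy:
    """A playing strategy: whether to go, when to go, and how long to stay out.

    ``decide``, ``plan_latency`` and ``plan_return`` each take
    ``(threat_level_index, tokens_in_hand)``.  Realised approach latencies add
    Gaussian noise (sd ``latency_noise_sd``) truncated below at zero;
    ``error_rate`` is the probability of an initial wrong left/right key,
    recorded as a control measure only.
    """

    decide: Callable[[int, int], bool]
    plan_latency: Callable[[int, int], float]
    plan_return: Callable[[int, int], float]
    latency_noise_sd: float = 0.05
    error_rate: float = 0.028


def draw_exposure_catch(
    rng: np.random.Generator,
    rate: float,
    exposure: float,
    bin_width: float = 0.02,
) -> bool:
    """Draw whether the predator wakes during ``exposure`` seconds outside safety.

    Wake-up events are determined independently per ``bin_width`` time bin with
    per-bin probability 1 - exp(-rate * bin_width), so that compounded over any
    whole number of bins the catch probability equals the continuous-time value
    1 - exp(-rate * t) exactly.  A fractional trailing bin uses the analogous
    probability for its actual duration.
    """
    if exposure <= 0:
        return False
    n_full = int(exposure / bin_width + 1e-9)
    p_bin = -math.expm1(-rate * bin_width)
    if n_full > 0 and np.any(rng.random(n_full) < p_bin):
        return True
    remainder = exposure - n_full * bin_width
    if remainder > 1e-9:
        return bool(rng.random() < -math.expm1(-rate * remainder))
    return False


def simulate_epoch(
    config: TaskConfig,
    policy: AgentPolicy,
    threat_level_index: int,
    rng: np.random.Generator,
    subject_id: int = 0,
    epoch_id: int = 0,
) -> list[dict]:
    """Simulate one epoch; returns one record per token opportunity.

    Tokens appear sequentially; each lives an exponential lifetime.  A go
    movement exposes the player for the planned return duration; the first
    predator activation in any 20 ms bin of that exposure catches the player,
    removes all tokens and truncates the epoch.  A token is collected iff the
    player reaches it before the lifetime expires and is not caught.
    """
    rate = config.threat_rates[threat_level_index]
    records: list[dict] = []
    tokens_in_hand = 0
    for token_index in range(1, config.tokens_per_epoch + 1):
        lifetime = rng.exponential(config.token_lifetime_mean)
        # inter-token interval (carryover + constant + variable); drawn for
        # fidelity to the game's pacing even though the trial table carries no
        # absolute timestamps
        _iti = config.iti_constant + rng.exponential(config.iti_variable_mean)
        rec = {
            "subject_id": subject_id,
            "epoch_id": epoch_id,
            "token_index": token_index,
            "threat_level_index": threat_level_index,
            "potential_loss": tokens_in_hand,
            "went": False,
            "approach_latency": np.nan,
            "return_latency": np.nan,
            "correct_direction": pd.NA,
            "token_collected": False,
            "caught": False,
        }
        if not policy.decide(threat_level_index, tokens_in_hand):
            records.append(rec)
            continue
        latency = float(policy.plan_latency(threat_level_index, tokens_in_hand))
        if policy.latency_noise_sd > 0:
            latency = max(latency + rng.normal(0.0, policy.latency_noise_sd), 0.0)
        exposure = float(policy.plan_return(threat_level_index, tokens_in_hand))
        caught = draw_exposure_catch(rng, rate, exposure, config.activation_bin)
        correct = bool(rng.random() >= policy.error_rate)
        collected = (not caught) and (latency <= lifetime)
        rec.update(
            went=True,
            approach_latency=latency,
            return_latency=exposure,
            correct_direction=correct,
            token_collected=collected,
            caught=caught,
        )
        records.append(rec)
        if caught:
            break  # all tokens lost; no further opportunities this epoch
        if collected:
            tokens_in_hand += 1
    return records


def simulate_experiment(
    config: TaskConfig,
    policy: AgentPolicy,
    n_subjects: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate ``n_subjects`` players, each over ``config.n_epochs`` epochs.

    Epochs are assigned to threat levels in balanced randomised order per
    subject.  The top-level seed is fanned out into independent per-subject
    streams, so growing the subject count never reshuffles existing subjects.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    n_levels = len(config.threat_levels)
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    all_records: list[dict] = []
    for subject_id, child in enumerate(children):
        rng = np.random.default_rng(child)
        levels = np.repeat(np.arange(n_levels), -(-config.n_epochs // n_levels))
        levels = rng.permutation(levels)[: config.n_epochs]
        for epoch_id, level in enumerate(levels):
            all_records.extend(
                simulate_epoch(
                    config, policy, int(level), rng,
                    subject_id=subject_id, epoch_id=epoch_id,
                )
            )
    df = pd.DataFrame.from_records(all_records, columns=TRIAL_COLUMNS)
    df["correct_direction"] = df["correct_direction"].astype("boolean")
    return df


def make_bdt_agent(
    prior: ThreatPrior,
    utilities: UtilityParams,
    gain_prior: GainPrior,
    noise_sd: float = 0.05,
    exposure: float = 0.1,
    level_scales: Sequence[float] = (0.5, 1.0, 1.5),
    loss_fn: Optional[Callable[[int, int], float]] = None,
    interval: tuple[float, float] = (0.0, 5.0),
    resolution: float = 1e-3,
    error_rate: float = 0.028,
) -> AgentPolicy:
    """Agent that plans each approach by maximising expected utility.

    For threat level ``i`` and ``T`` tokens in hand the agent builds a decision
    model with loss utility ``loss_fn(i, T)`` (default: -T, the tokens at
    stake) and threat prior scaled by ``level_scales[i]`` — higher threat
    levels scale up the whole loss-probability curve, the comparative-statics
    mode under which larger threat delays the optimum.  It goes iff the
    achieved expected utility is positive; with zero potential loss the gain
    term alone drives the plan and the agent moves at the interval minimum.
    """
    if loss_fn is None:
        loss_fn = lambda level, tokens: -float(tokens)

    @lru_cache(maxsize=None)
    def _plan(level: int, tokens: int) -> OptimalLatency:
        loss = float(loss_fn(level, tokens))
        if loss >= 0.0:
            # nothing at stake: expected utility reduces to the decaying gain,
            # maximised at the earliest allowed latency
            t0 = interval[0]
            g = float(utilities.gain * gain_prior.value(t0))
            return OptimalLatency(t1=t0, utility=g, boundary=True)
        dm = DecisionModel(
            utilities=UtilityParams(gain=utilities.gain, loss=loss),
            gain_prior=gain_prior,
            threat=prior,
            delta_t=exposure,
            threat_scale=float(level_scales[level]),
        )
        return optimal_latency(dm, interval=interval, resolution=resolution)

    return AgentPolicy(
        decide=lambda level, tokens: _plan(level, tokens).utility > 0.0,
        plan_latency=lambda level, tokens: _plan(level, tokens).t1,
        plan_return=lambda level, tokens: exposure,
        latency_noise_sd=noise_sd,
        error_rate=error_rate,
    )


def make_fixed_agent(
    latency: float = 0.5,
    exposure: float = 0.1,
    noise_sd: float = 0.05,
    error_rate: float = 0.028,
) -> AgentPolicy:
    """Always goes, at a fixed planned latency — a null agent with no condition effects."""
    return AgentPolicy(
        decide=lambda level, tokens: True,
        plan_latency=lambda level, tokens: latency,
        plan_return=lambda level, tokens: exposure,
        latency_noise_sd=noise_sd,
        error_rate=error_rate,
    )


def make_never_go_agent() -> AgentPolicy:
    """Never leaves the safe place."""
    return AgentPolicy(
        decide=lambda level, tokens: False,
        plan_latency=lambda level, tokens: 0.0,
        plan_return=lambda level, tokens: 0.0,
        latency_noise_sd=0.0,
        error_rate=0.0,
    )


def make_random_agent(
    go_prob: float = 0.8,
    latency_range: tuple[float, float] = (0.2, 1.5),
    exposure: float = 0.1,
    seed: int = 0,
) -> AgentPolicy:
    """Goes with fixed probability at a uniform random latency (policy-level rng)."""
    rng = np.random.default_rng(seed)
    return AgentPolicy(
        decide=lambda level, tokens: bool(rng.random() < go_prob),
        plan_latency=lambda level, tokens: float(rng.uniform(*latency_range)),
        plan_return=lambda level, tokens: exposure,
        latency_noise_sd=0.0,
        error_rate=0.028,
    )
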