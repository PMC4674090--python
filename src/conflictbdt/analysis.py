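"""Behavioural analysis: implicit choices, latency filtering, condition means, trends.

The game forces sequential collection, so observed choices are both
overspecified (a player who stops repeats the same no-go) and incomplete (the
later tokens are never shown).  :func:`reconstruct_choices` expands every
non-caught epoch into six implicit go/no-go data points.  Latency analyses use
response windows to exclude extreme values and drop the rarely-collected last
token, then estimate condition means by a two-stage (subject, then group)
average and test linear trends of approach latency in threat level and
potential loss with a random-subject-intercept linear model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "DataError",
    "ConditionEstimate",
    "TrendResult",
    "reconstruct_choices",
    "filter_latencies",
    "condition_means",
    "trend_test",
    "go_rate_table",
]


class DataError(ValueError):
    """Malformed trial data (e.g. non-contiguous token indices within an epoch)."""


def reconstruct_choices(trials: pd.DataFrame, n_slots: int = 6) -> pd.DataFrame:
    """Expand each non-caught epoch into six implicit choice records.

    Record ``token_slot = s`` is True iff the player collected at least ``s``
    tokens in that epoch: collecting n tokens then stopping means implicit
    no-go on slots n+1..6.  Epochs ending in a catch are excluded — how many
    tokens the player would have chosen to collect cannot be reconstructed.
    """
    out = []
    for (subject, epoch), grp in trials.groupby(["subject_id", "epoch_id"], sort=True):
        idx = grp["token_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise DataError(
                f"epoch {epoch} of subject {subject}: non-contiguous token indices {idx}"
            )
        if bool(grp["caught"].any()):
            continue
        n_collected = int(grp["token_collected"].sum())
        level = int(grp["threat_level_index"].iloc[0])
        for slot in range(1, n_slots + 1):
            out.append(
                {
                    "subject_id": subject,
                    "epoch_id": epoch,
                    "token_slot": slot,
                    "threat_level_index": level,
                    "chose_at_least": slot <= n_collected,
                }
            )
    return pd.DataFrame(
        out,
        columns=["subject_id", "epoch_id", "token_slot", "threat_level_index", "chose_at_least"],
    )


def filter_latencies(
    trials: pd.DataFrame,
    approach_window: tuple[float, float] = (0.150, 2.000),
    return_window: tuple[float, float] = (0.0, 2.000),
    drop_last_token: bool = True,
    include_caught_epochs: bool = True,
    last_token: int = 6,
) -> tuple[pd.DataFrame, dict]:
    """Keep go trials with latencies inside the response windows.

    Approach latency must lie strictly inside ``approach_window`` and return
    latency strictly inside ``return_window`` (both exclusive, guarding the
    estimates against extreme values).  The last token slot is dropped because
    players rarely collect it and its design cells are unreliable.  Go trials
    from epochs that later ended in a catch are kept by default (their
    latencies were produced before the catch); set ``include_caught_epochs``
    False to exclude whole caught epochs instead.

    Returns the filtered table and an exclusion report with per-filter
    percentages among go trials.
    """
    go = trials[trials["went"]].copy()
    n_go = len(go)
    if not include_caught_epochs:
        caught_epochs = trials.loc[trials["caught"], ["subject_id", "epoch_id"]]
        key = pd.MultiIndex.from_frame(caught_epochs)
        go = go[~pd.MultiIndex.from_frame(go[["subject_id", "epoch_id"]]).isin(key)]
    if drop_last_token:
        go = go[go["token_index"] < last_token]
    n_after_slot = len(go)
    ok_approach = (go["approach_latency"] > approach_window[0]) & (
        go["approach_latency"] < approach_window[1]
    )
    ok_return = (go["return_latency"] > return_window[0]) & (
        go["return_latency"] < return_window[1]
    )
    report = {
        "n_go_trials": n_go,
        "n_after_slot_drop": n_after_slot,
        "pct_excluded_approach": 100.0 * float((~ok_approach).sum()) / n_after_slot
        if n_after_slot
        else 0.0,
        "pct_excluded_return": 100.0 * float((~ok_return).sum()) / n_after_slot
        if n_after_slot
        else 0.0,
    }
    filtered = go[ok_approach & ok_return].copy()
    report["n_retained"] = len(filtered)
    return filtered, report


@dataclass(frozen=True)
class ConditionEstimate:
    """Per (threat level x potential loss) cell statistics."""

    threat_level_index: int
    potential_loss: int
    mean_approach_latency: float
    mean_return_latency: float
    go_rate: float
    n_obs: int
    n_subjects: int
    missing: bool


def condition_means(
    filtered: pd.DataFrame,
    trials: Optional[pd.DataFrame] = None,
    max_loss: Optional[int] = None,
) -> pd.DataFrame:
    """Two-stage condition means: average per subject and cell, then over subjects.

    Averaging within subject first bounds any one subject's influence by
    1/n_subjects even when trial counts are wildly unbalanced, and cells
    missing in some subjects are averaged only over the subjects that
    contribute.  Empty cells are flagged missing, never imputed.  If the full
    trial table is supplied, a per-cell go rate (proportion of opportunities
    answered with a go) is added.
    """
    levels = sorted(filtered["threat_level_index"].unique()) if len(filtered) else []
    if max_loss is None:
        max_loss = int(filtered["potential_loss"].max()) if len(filtered) else 0
    rows = []
    subj_cell = (
        filtered.groupby(["subject_id", "threat_level_index", "potential_loss"])
        .agg(
            app=("approach_latency", "mean"),
            ret=("return_latency", "mean"),
            n=("approach_latency", "size"),
        )
        .reset_index()
    )
    go_lookup = None
    if trials is not None:
        go_lookup = (
            trials.groupby(["threat_level_index", "potential_loss"])["went"]
            .mean()
            .to_dict()
        )
    for level in levels:
        for loss in range(0, max_loss + 1):
            cell = subj_cell[
                (subj_cell["threat_level_index"] == level)
                & (subj_cell["potential_loss"] == loss)
            ]
            n_subjects = len(cell)
            missing = n_subjects == 0
            rows.append(
                {
                    "threat_level_index": level,
                    "potential_loss": loss,
                    "mean_approach_latency": float(cell["app"].mean()) if not missing else np.nan,
                    "mean_return_latency": float(cell["ret"].mean()) if not missing else np.nan,
                    "go_rate": float(go_lookup.get((level, loss), np.nan)) if go_lookup else np.nan,
                    "n_obs": int(cell["n"].sum()),
                    "n_subjects": n_subjects,
                    "missing": missing,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendResult:
    """Linear-trend estimates for threat level and potential loss effects."""

    slope_threat: float  # seconds per threat step
    slope_loss: float  # seconds per token at stake
    slope_interaction: float
    se_threat: float
    se_loss: float
    f_threat: float
    f_loss: float
    p_threat: float
    p_loss: float
    df: int  # conservative denominator dof: N - (fixed + random effects)
    n_obs: int
    sigma_resid: float
    sigma_subject: float
    method: str  # 'profiled-gls' or 'demeaned-ols' fallback


def _profile_neg_loglik(log_theta, y, X, groups_idx, group_sizes):
    """Profile (-2 log) marginal likelihood of the random-intercept model at theta.

    theta = var(subject intercept) / var(residual).  Marginal covariance per
    subject block is sigma2 * (I + theta * J); its inverse and log-determinant
    have closed forms, so beta and sigma2 profile out and only theta is
    searched numerically.
    """
    theta = np.exp(log_theta)
    n, k = X.shape
    XtVX = np.zeros((k, k))
    XtVy = np.zeros(k)
    ytVy = 0.0
    logdet = 0.0
    for g, m in enumerate(group_sizes):
        sl = groups_idx[g]
        Xg, yg = X[sl], y[sl]
        w = theta / (1.0 + theta * m)
        Xs, ys = Xg.sum(axis=0), yg.sum()
        XtVX += Xg.T @ Xg - w * np.outer(Xs, Xs)
        XtVy += Xg.T @ yg - w * Xs * ys
        ytVy += yg @ yg - w * ys * ys
        logdet += np.log1p(theta * m)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - beta @ XtVy
    sigma2 = max(rss / n, 1e-300)
    nll = n * np.log(sigma2) + logdet + n
    return nll, beta, sigma2, XtVX


def trend_test(
    filtered: pd.DataFrame,
    response: str = "approach",
    log_latency: bool = False,
) -> TrendResult:
    """Random-intercept linear trend test of latency on threat level and loss.

    Fits ``latency ~ threat + loss + threat:loss + (1 | subject)`` with threat
    level and potential loss entered as linear (numeric) contrasts, centered at
    their sample means so the main-effect slopes read as average marginal
    trends rather than trends at the zero cell.  The single
    intercept-variance component is profiled by a one-dimensional likelihood
    search; fixed effects then come from generalised least squares.  F-type
    statistics use the conservative denominator degrees of freedom
    ``N - K`` where K counts all modelled fixed and random effects.  If the
    variance profile fails to converge the fit falls back to subject-demeaned
    ordinary least squares, flagged in ``method``.
    """
    col = {"approach": "approach_latency", "return": "return_latency"}[response]
    data = filtered.dropna(subset=[col])
    if data["subject_id"].nunique() < 2:
        raise ValueError("trend test needs at least 2 subjects")
    if (
        data["threat_level_index"].nunique() < 2
        or data["potential_loss"].nunique() < 2
    ):
        raise ValueError("trend test needs >= 2 levels of each factor")

    y = data[col].to_numpy(dtype=float)
    if log_latency:
        y = np.log(y)
    threat = data["threat_level_index"].to_numpy(dtype=float)
    loss = data["potential_loss"].to_numpy(dtype=float)
    threat_c = threat - threat.mean()
    loss_c = loss - loss.mean()
    X = np.column_stack([np.ones_like(y), threat_c, loss_c, threat_c * loss_c])
    subjects, subj_codes = np.unique(data["subject_id"].to_numpy(), return_inverse=True)
    order = np.argsort(subj_codes, kind="stable")
    y, X, subj_codes = y[order], X[order], subj_codes[order]
    group_sizes = np.bincount(subj_codes)
    bounds = np.concatenate([[0], np.cumsum(group_sizes)])
    groups_idx = [slice(bounds[g], bounds[g + 1]) for g in range(len(group_sizes))]

    n, k_fixed = X.shape
    n_subjects = len(subjects)
    K = k_fixed + n_subjects
    df = n - K

    method = "profiled-gls"
    try:
        res = minimize_scalar(
            lambda lt: _profile_neg_loglik(lt, y, X, groups_idx, group_sizes)[0],
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise RuntimeError("variance profile search did not converge")
        theta = float(np.exp(res.x))
        _, beta, sigma2, XtVX = _profile_neg_loglik(res.x, y, X, groups_idx, group_sizes)
        cov = sigma2 * np.linalg.inv(XtVX)
        sigma_resid = float(np.sqrt(sigma2))
        sigma_subject = float(np.sqrt(theta * sigma2))
    except (RuntimeError, np.linalg.LinAlgError):
        # fallback: remove subject means, then OLS on the demeaned data
        method = "demeaned-ols"
        y_d = y - np.concatenate([np.full(m, y[sl].mean()) for sl, m in zip(groups_idx, group_sizes)])
        X_d = X.copy()
        for sl in groups_idx:
            X_d[sl, 1:] = X[sl, 1:] - X[sl, 1:].mean(axis=0)
        beta, *_ = np.linalg.lstsq(X_d, y_d, rcond=None)
        resid = y_d - X_d @ beta
        sigma2 = float(resid @ resid / max(df, 1))
        cov = sigma2 * np.linalg.pinv(X_d.T @ X_d)
        sigma_resid = float(np.sqrt(sigma2))
        sigma_subject = float("nan")

    se = np.sqrt(np.diag(cov))
    f_stats = (beta / se) ** 2
    p = stats.f.sf(f_stats, 1, max(df, 1))
    return TrendResult(
        slope_threat=float(beta[1]),
        slope_loss=float(beta[2]),
        slope_interaction=float(beta[3]),
        se_threat=float(se[1]),
        se_loss=float(se[2]),
        f_threat=float(f_stats[1]),
        f_loss=float(f_stats[2]),
        p_threat=float(p[1]),
        p_loss=float(p[2]),
        df=int(df),
        n_obs=int(n),
        sigma_resid=sigma_resid,
        sigma_subject=sigma_subject,
        method=method,
    )


def go_rate_table(choices: pd.DataFrame) -> pd.DataFrame:
    """Proportion of implicit go choices per (threat level x token slot)."""
    if len(choices) == 0:
        return pd.DataFrame(
            columns=["threat_level_index", "token_slot", "go_rate", "n_obs"]
        )
    out = (
        choices.groupby(["threat_level_index", "token_slot"])["chose_at_least"]
        .agg(go_rate="mean", n_obs="size")
        .reset_index()
    )
    out["go_rate"] = out["go_rate"].astype(float)
    return out
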