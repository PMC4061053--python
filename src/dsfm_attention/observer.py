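"""Simulated observer for the two-interval (2IFC) speed-discrimination task.

The observer compares noisy internal estimates of log rotation speed across
the two intervals, giving a cumulative-Gaussian psychometric function of the
log speed ratio with a 0.5 guessing floor (2IFC) and a lapse rate:

    P(correct | ratio r) = lapse/2 + (1 - lapse) * Phi(|log r| / (sigma * sqrt(2)))

``sigma`` is the standard deviation of the internal log-speed noise for a
single interval (hence the sqrt(2) for the difference of two estimates).
When the spatial cue is invalid the effective sigma is inflated by
``attention_effect``, modeling the cost of discriminating an uncued
cylinder.  Defaults are calibrated so that the true 75%-correct point is a
speed factor of about 1.41 and invalid-cue performance at that factor is
near chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ObserverModel",
    "ThresholdEstimate",
    "ThresholdError",
    "p_correct",
    "true_threshold",
    "simulate_trials",
    "estimate_threshold",
    "proportion_ci",
    "group_permutation_test",
    "summarize",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class ObserverModel:
    sigma: float = 0.35          # SD of internal log-speed noise (log units)
    lapse: float = 0.02          # lapse rate in [0, 1]
    attention_effect: float = 9.0  # sigma multiplier when the cue is invalid
    guess_floor: float = 0.5     # 2IFC chance level (fixed)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.attention_effect <= 0:
            raise ValueError("attention_effect must be positive")


def _effective_sigma(model: ObserverModel, cue_valid) -> np.ndarray:
    valid = np.asarray(cue_valid, dtype=bool)
    return np.where(valid, model.sigma, model.sigma * model.attention_effect)


def p_correct(speed_ratio, model: ObserverModel, cue_valid=True):
    """Probability of a correct 2IFC response at the given speed ratio(s).

    ``sigma = 0`` gives a step observer (perfect above ratio 1, chance at 1);
    ``sigma = inf`` gives a pure guesser at 0.5 everywhere.
    """
    r = np.asarray(speed_ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("speed_ratio must be positive")
    sig = _effective_sigma(model, cue_valid)
    x = np.abs(np.log(r))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sig > 0, x / (sig * _SQRT2), np.where(x > 0, np.inf, 0.0))
        z = np.where(np.isfinite(sig), z, 0.0)  # infinite noise -> guessing
    p = model.lapse / 2.0 + (1.0 - model.lapse) * stats.norm.cdf(z)
    return p if p.ndim else float(p)


def true_threshold(model: ObserverModel, criterion: float = 0.75,
                   cue_valid: bool = True) -> float:
    """Closed-form speed factor at which ``p_correct`` equals ``criterion``."""
    if not 0.5 < criterion < 1.0:
        raise ValueError("criterion must lie in (0.5, 1)")
    target = (criterion - model.lapse / 2.0) / (1.0 - model.lapse)
    if not 0.5 < target < 1.0:
        raise ValueError("criterion unreachable at this lapse rate")
    sig = float(_effective_sigma(model, cue_valid))
    return math.exp(sig * _SQRT2 * stats.norm.ppf(target))


def simulate_trials(trials, model: ObserverModel, seed: int) -> pd.DataFrame:
    """Bernoulli responses for a sequence of trials.

    ``trials`` is a DataFrame with a ``speed_ratio`` column (optional
    ``cue_valid``, default valid), or an event table from the block design,
    in which case the per-trial ratio is the speed factor on change trials
    and 1.0 otherwise and passive trials are dropped.  Returns a copy with
    ``p_correct`` and ``correct`` columns.
    """
    df = trials.copy()
    if "speed_ratio" not in df.columns:
        if "speed_change" not in df.columns:
            raise ValueError("trials need a speed_ratio or speed_change column")
        df = df[~df["condition"].str.startswith("passive")].copy()
        df["speed_ratio"] = np.where(df["speed_change"], df["speed_factor"], 1.0)
    cue_valid = df["cue_valid"].to_numpy() if "cue_valid" in df.columns else True
    rng = np.random.default_rng(seed)
    p = np.asarray(p_correct(df["speed_ratio"].to_numpy(), model, cue_valid))
    df["p_correct"] = p
    df["correct"] = rng.random(len(df)) < p
    return df


@dataclass
class ThresholdEstimate:
    threshold: float          # estimated speed factor at the criterion
    criterion: float
    sigma_hat: float
    lapse_hat: float
    n_trials: int
    trace: pd.DataFrame       # per-trial (ratio, correct, step) staircase record
    converged: bool


class ThresholdError(RuntimeError):
    """Raised when the staircase/fit fails; carries the staircase trace."""

    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


def _fit_psychometric(ratios: np.ndarray, correct: np.ndarray,
                      criterion: float) -> tuple[float, float, float]:
    """Maximum-likelihood cumulative-Gaussian fit; returns (thr, sigma, lapse)."""
    x = np.abs(np.log(ratios))

    def nll(params):
        log_sigma, lapse = params
        sigma = math.exp(log_sigma)
        p = lapse / 2.0 + (1.0 - lapse) * stats.norm.cdf(x / (sigma * _SQRT2))
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return -np.sum(np.where(correct, np.log(p), np.log(1.0 - p)))

    res = optimize.minimize(nll, x0=[math.log(0.3), 0.02],
                            bounds=[(math.log(1e-3), math.log(5.0)), (0.0, 0.2)],
                            method="L-BFGS-B")
    if not res.success:
        raise RuntimeError(f"psychometric fit failed: {res.message}")
    sigma_hat = math.exp(res.x[0])
    lapse_hat = float(res.x[1])
    thr = true_threshold(ObserverModel(sigma=sigma_hat, lapse=lapse_hat),
                         criterion)
    return thr, sigma_hat, lapse_hat


def estimate_threshold(model: ObserverModel | None = None,
                       data: pd.DataFrame | None = None,
                       criterion: float = 0.75,
                       method: str = "staircase",
                       n_trials: int = 1295,
                       seed: int = 0,
                       start_factor: float = 1.8) -> ThresholdEstimate:
    """Estimate the speed factor at the criterion proportion correct.

    method="analytic"  : invert the model's psychometric function exactly.
    method="staircase" : run a 2-down-1-up adaptive staircase (converging
        near 70.7% correct) on the simulated observer, then fit a
        cumulative Gaussian by maximum likelihood to all staircase trials
        and read off the criterion point.  1295 trials is the default
        training length.
    method="fit"       : maximum-likelihood fit to supplied constant-stimuli
        ``data`` (columns ``speed_ratio``, ``correct``).
    """
    if not 0.5 < criterion < 1.0:
        raise ValueError("criterion must lie in (0.5, 1)")
    if method == "analytic":
        if model is None:
            raise ValueError("analytic method needs a model")
        thr = true_threshold(model, criterion)
        return ThresholdEstimate(thr, criterion, model.sigma, model.lapse, 0,
                                 pd.DataFrame(), True)
    if method == "fit":
        if data is None:
            raise ValueError("fit method needs data")
        thr, s, l = _fit_psychometric(data["speed_ratio"].to_numpy(),
                                      data["correct"].to_numpy(), criterion)
        return ThresholdEstimate(thr, criterion, s, l, len(data), pd.DataFrame(), True)
    if method != "staircase":
        raise ValueError(f"unknown method {method!r}")
    if model is None:
        raise ValueError("staircase method needs a model")

    rng = np.random.default_rng(seed)
    log_f = math.log(start_factor)
    step = 0.15          # initial step in log-factor units
    min_step = 0.02
    n_correct_run = 0
    last_dir = 0
    rows = []
    for t in range(n_trials):
        ratio = math.exp(log_f)
        correct = bool(rng.random() < p_correct(ratio, model))
        rows.append({"trial": t, "speed_ratio": ratio,
                     "correct": correct, "step": step})
        if correct:
            n_correct_run += 1
            if n_correct_run >= 2:          # 2-down: make it harder
                n_correct_run = 0
                if last_dir == +1:          # reversal -> shrink step
                    step = max(step / 2.0, min_step)
                log_f = max(log_f - step, 1e-3)
                last_dir = -1
        else:                               # 1-up: make it easier
            n_correct_run = 0
            if last_dir == -1:
                step = max(step / 2.0, min_step)
            log_f = min(log_f + step, math.log(8.0))
            last_dir = +1
    trace = pd.DataFrame(rows)
    try:
        thr, s, l = _fit_psychometric(trace["speed_ratio"].to_numpy(),
                                      trace["correct"].to_numpy(), criterion)
    except RuntimeError as err:
        raise ThresholdError(str(err), trace) from err
    if not 1.0 < thr < 8.0:
        raise ThresholdError(f"threshold estimate {thr:.3f} out of range", trace)
    return ThresholdEstimate(thr, criterion, s, l, n_trials, trace, True)


def proportion_ci(correct, level: float = 0.99,
                  method: str = "exact") -> tuple[float, float, float]:
    """Proportion correct with a binomial confidence interval.

    method="exact" uses the Clopper-Pearson interval, "normal" the Wald
    approximation.  Returns ``(mean, lower, upper)``.
    """
    correct = np.asarray(correct, dtype=bool)
    n = correct.size
    if n == 0:
        raise ValueError("empty input")
    k = int(correct.sum())
    mean = k / n
    if method == "exact":
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=level,
                                                 method="exact")
        return mean, float(ci.low), float(ci.high)
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(mean * (1.0 - mean) / n)
        return mean, max(0.0, mean - half), min(1.0, mean + half)
    raise ValueError(f"unknown method {method!r}")


def summarize(results: pd.DataFrame, by=None, level: float = 0.99,
              method: str = "exact") -> pd.DataFrame:
    """Proportion correct (with CI) overall or per group."""
    def _row(g):
        m, lo, hi = proportion_ci(g["correct"].to_numpy(), level, method)
        return pd.Series({"n": len(g), "proportion": m,
                          "ci_low": lo, "ci_high": hi})
    if by is None:
        return _row(results).to_frame().T
    return (results.groupby(by, dropna=False)
            .apply(_row, include_groups=False).reset_index())


def group_permutation_test(correct, groups, n_perm: int = 5000,
                           seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Permutation test for any difference in proportion correct across groups.

    The statistic is the variance of group means; group labels are permuted.
    Returns ``(statistic, p_value, null_distribution)``.  This is the
    reduced, non-parametric counterpart of a factorial ANOVA on behavioral
    breakdowns (similarity, side, session, ...).
    """
    correct = np.asarray(correct, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least two groups")

    def stat(g):
        return float(np.var([correct[g == lab].mean() for lab in labels]))

    obs = stat(groups)
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(groups)) for _ in range(n_perm)])
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return obs, p, null
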