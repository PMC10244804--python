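"""Model-evaluation statistics.

RMSE and relative RMSE with the four-class accuracy rubric, the
observed-vs-simulated 1:1-line regression test, and the LMG (averaged
sequential R^2) relative-importance decomposition used to rank the
environmental drivers of xylem water potential.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FitMetrics",
    "rmse",
    "rrmse",
    "classify_accuracy",
    "one_to_one_test",
    "OneToOneResult",
    "lmg_importance",
    "evaluate_stream",
]


@dataclass(frozen=True)
class FitMetrics:
    """RMSE (variable units), RRMSE (%), sample size, accuracy class."""

    rmse: float
    rrmse: float
    n: int
    accuracy_class: str


def _as_arrays(obs, sim) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float)
    s = np.asarray(sim, dtype=float)
    if o.shape != s.shape:
        raise ValueError(f"length mismatch: obs {o.shape} vs sim {s.shape}")
    if o.size == 0:
        raise ValueError("empty observation set")
    return o, s


def rmse(obs, sim) -> float:
    """Root mean square error sqrt(sum((O - S)^2) / n)."""
    o, s = _as_arrays(obs, sim)
    return float(np.sqrt(np.mean((o - s) ** 2)))


def rrmse(obs, sim) -> float:
    """Relative RMSE (%): RMSE over the magnitude of the observed mean.

    The magnitude keeps the index positive for variables measured on a
    negative scale (water potentials), matching how relative errors of
    such streams are reported.
    """
    o, s = _as_arrays(obs, sim)
    mean_obs = float(np.mean(o))
    if mean_obs == 0.0:
        raise ValueError("RRMSE undefined: observed mean is zero")
    return rmse(o, s) / abs(mean_obs) * 100.0


ACCURACY_BANDS = (
    (10.0, "excellent"),
    (20.0, "good"),
    (30.0, "fair"),
)


def classify_accuracy(rrmse_pct: float) -> str:
    """Accuracy rubric: <10% excellent, [10,20) good, [20,30) fair, >=30 poor."""
    if rrmse_pct < 0:
        raise ValueError("RRMSE must be >= 0")
    for upper, label in ACCURACY_BANDS:
        if rrmse_pct < upper:
            return label
    return "poor"


@dataclass(frozen=True)
class OneToOneResult:
    """OLS of observed on simulated with t-tests against the 1:1 line."""

    slope: float
    intercept: float
    slope_differs: bool
    intercept_differs: bool
    p_slope: float
    p_intercept: float


def one_to_one_test(obs, sim, alpha: float = 0.05) -> OneToOneResult:
    """Test whether the obs~sim regression departs from the 1:1 line.

    Ordinary least squares of observed on simulated; separate t-tests of
    slope = 1 and intercept = 0 at level ``alpha`` (the per-coefficient
    reading of an ANCOVA-style 1:1 comparison).
    """
    o, s = _as_arrays(obs, sim)
    if o.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(s) == 0:
        raise ValueError("degenerate predictor: simulated values are constant")
    x = sm.add_constant(s)
    fit = sm.OLS(o, x).fit()
    if fit.ssr <= 1e-14 * max(float(np.sum(o**2)), 1.0):
        # perfect fit: the t-tests are degenerate; compare the coefficients
        # to the 1:1 line directly
        slope, intercept = float(fit.params[1]), float(fit.params[0])
        scale = max(abs(o).max(), 1.0)
        slope_off = abs(slope - 1.0) > 1e-10
        int_off = abs(intercept) > 1e-10 * scale
        return OneToOneResult(
            slope=slope,
            intercept=intercept,
            slope_differs=slope_off,
            intercept_differs=int_off,
            p_slope=0.0 if slope_off else 1.0,
            p_intercept=0.0 if int_off else 1.0,
        )
    p_int = float(fit.t_test([1.0, 0.0]).pvalue)
    p_slope = float(fit.t_test(([0.0, 1.0], 1.0)).pvalue)
    return OneToOneResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_differs=p_slope < alpha,
        intercept_differs=p_int < alpha,
        p_slope=p_slope,
        p_intercept=p_int,
    )


def _r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    design = np.column_stack([np.ones(len(y)), x[:, cols]])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("exactly collinear predictors")
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def lmg_importance(y, predictors) -> pd.Series:
    """LMG relative importance: R^2 shares by averaging sequential gains.

    For each predictor the increase in R^2 when it enters the model is
    averaged over all orderings of the predictors; the shares sum to the
    full-model R^2. Exhaustive enumeration, capped at 5 predictors.
    ``predictors`` is a DataFrame (or 2-D array; columns are predictors).
    """
    x_df = pd.DataFrame(predictors)
    y = np.asarray(y, dtype=float)
    p = x_df.shape[1]
    if p < 1 or p > 5:
        raise ValueError("lmg_importance supports 1 to 5 predictors")
    if len(y) <= p + 1:
        raise ValueError("need n > p + 1 observations")
    x = x_df.to_numpy(dtype=float)
    r2_cache: dict[tuple[int, ...], float] = {}

    def r2_of(cols: tuple[int, ...]) -> float:
        key = tuple(sorted(cols))
        if key not in r2_cache:
            r2_cache[key] = _r2(y, x, key)
        return r2_cache[key]

    shares = np.zeros(p)
    perms = list(itertools.permutations(range(p)))
    for order in perms:
        seen: tuple[int, ...] = ()
        for idx in order:
            gain = r2_of(seen + (idx,)) - r2_of(seen)
            shares[idx] += gain
            seen = seen + (idx,)
    shares /= len(perms)
    return pd.Series(shares, index=x_df.columns, name="lmg_share")


def evaluate_stream(obs, sim) -> FitMetrics:
    """RMSE/RRMSE/accuracy-class summary for one observation stream."""
    o, s = _as_arrays(obs, sim)
    e = rmse(o, s)
    r = rrmse(o, s)
    return FitMetrics(rmse=e, rrmse=r, n=int(o.size), accuracy_class=classify_accuracy(r))
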