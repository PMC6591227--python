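"""Adaptation-time estimation from growth curves.

A treated population shows up to three growth phases: suppression (flat),
regrowth, and saturation.  The adaptation time follows a three-way rule:

* if no moving-window (default 3-timepoint) local growth rate ever falls to
  0 or below, the population was never suppressed and the adaptation time
  is exactly 0;
* if the population completely dies off, the adaptation time is +infinity;
* otherwise the Baranyi-Roberts environmental-adjustment growth model is
  fitted to log counts with a derivative-free (Powell) minimizer and the
  adaptation time is the time at which the fitted curve reaches the
  midpoint between its fitted baseline and plateau (half-saturation on the
  log scale).

Growth rates are local slopes of ln(count + 1) so that zero counts are
tolerated; the +1 pseudocount is a documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._stats import mann_whitney

EXTINCTION_FLOOR = 1.0


class BaranyiFitError(RuntimeError):
    """No Powell start converged to a usable optimum."""


@dataclass
class GrowthCurve:
    """Cell-count time series for one replicate of one condition."""

    t: np.ndarray
    count: np.ndarray
    replicate_id: str = ""
    condition: str = ""
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if len(self.t) != len(self.count):
            raise ValueError("t and count must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.t, "count": self.count,
                             "replicate": self.replicate_id,
                             "condition": self.condition})


def read_growth_curves(path) -> list[GrowthCurve]:
    """Read growth-curve CSV (time_days, count, replicate, condition)."""
    df = pd.read_csv(path)
    for col in ("condition", "replicate"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    out = []
    for (cond, rep), g in df.groupby(["condition", "replicate"], sort=False):
        g = g.sort_values("time_days")
        out.append(GrowthCurve(g["time_days"].to_numpy(), g["count"].to_numpy(),
                               replicate_id=str(rep), condition=str(cond)))
    return out


@dataclass
class AdaptationResult:
    adaptation_time: float            # days; 0, finite, or +inf
    half_saturation_time: float
    suppressed: bool
    fit_params: dict | None = None    # y0, y_max, mu_max, h0 (log-count scale)
    fit_loss: float = float("nan")
    replicate_id: str = ""
    condition: str = ""


# ---------------------------------------------------------------------------
# moving-window growth rates and suppression
# ---------------------------------------------------------------------------

def moving_growth_rate(curve: GrowthCurve, window: int = 3) -> np.ndarray:
    """Local slope of ln(count + 1) over each consecutive ``window`` points.

    Returns a series of length len(t) - window + 1.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    if len(curve) < window:
        raise ValueError(f"need at least {window} timepoints")
    y = np.log(curve.count + 1.0)
    n = len(curve) - window + 1
    rates = np.empty(n)
    for i in range(n):
        tt = curve.t[i:i + window]
        yy = y[i:i + window]
        rates[i] = np.polyfit(tt, yy, 1)[0]
    return rates


def classify_suppression(rates: np.ndarray) -> bool:
    """True iff any moving-window growth rate fell to 0 or below."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate series")
    return bool(np.min(rates) <= 0.0)


def is_extinct(curve: GrowthCurve, window: int = 3,
               floor: float = EXTINCTION_FLOOR) -> bool:
    """Complete die-off: final count at/below floor with no recovery.

    Recovery means some window growth rate after the count minimum is
    positive.
    """
    if curve.count[-1] > floor:
        return False
    rates = moving_growth_rate(curve, window)
    i_min = int(np.argmin(curve.count))
    # windows starting at or after the minimum
    post = rates[min(i_min, len(rates) - 1):]
    return not np.any(post > 0)


def has_recovered(curve: GrowthCurve, factor: float = 2.0) -> bool:
    """Did the population regrow appreciably after its minimum?

    Recovery requires the post-minimum maximum to exceed ``factor`` times
    the minimum count (with a pseudocount so extinct minima do not divide
    by zero).  Suppressed curves that never recover — whether they died off
    or merely stagnated — carry an infinite adaptation time.
    """
    i_min = int(np.argmin(curve.count))
    c_min = curve.count[i_min]
    post_max = np.max(curve.count[i_min:])
    return post_max >= factor * (c_min + 1.0)


# ---------------------------------------------------------------------------
# Baranyi-Roberts model
# ---------------------------------------------------------------------------

def baranyi_log_counts(t: np.ndarray, y0: float, y_max: float,
                       mu_max: float, h0: float) -> np.ndarray:
    """Baranyi-Roberts solution on the log-count scale.

    A(t) = t + (1/mu) ln(e^{-mu t} + e^{-h0} - e^{-mu t - h0})
    y(t) = y0 + mu A(t) - ln(1 + (e^{mu A(t)} - 1) / e^{y_max - y0})

    h0 encodes the physiological lag (lag time = h0 / mu_max).
    """
    t = np.asarray(t, dtype=float)
    mu = mu_max
    # A(t) = t + (1/mu) log(e^{-mu t} + e^{-h0}(1 - e^{-mu t}))
    inner = np.exp(-mu * t) + np.exp(-h0) * (1.0 - np.exp(-mu * t))
    a = t + np.log(np.clip(inner, 1e-300, None)) / mu
    ma = np.clip(mu * a, None, 700.0)  # overflow guard far past saturation
    span = y_max - y0
    return y0 + ma - np.log1p((np.exp(ma) - 1.0) * np.exp(-span))


def _baranyi_objective(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    y0, y_max, log_mu, log_h0 = theta
    if y_max <= y0:
        return 1e12
    pred = baranyi_log_counts(t, y0, y_max, np.exp(log_mu), np.exp(log_h0))
    return float(np.sum((pred - y) ** 2))


def fit_baranyi(curve: GrowthCurve, window: int = 3, n_starts: int = 8,
                seed: int = 0, xtol: float = 1e-8) -> AdaptationResult:
    """Fit the Baranyi-Roberts model to log counts and extract timings.

    Multi-start Powell minimization of the squared error on the
    ln(count + 1) scale; the adaptation time is where the best fit crosses
    (y0 + y_max)/2.  Requires a suppressed, non-extinct curve with at least
    5 timepoints; sentinel routing for unsuppressed/extinct curves lives in
    :func:`estimate_adaptation`.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 timepoints for a Baranyi fit")
    t = curve.t
    y = np.log(curve.count + 1.0)
    rates = moving_growth_rate(curve, window)

    y0_init = float(np.min(y[: max(3, len(y) // 4)]))
    ymax_init = float(np.max(y))
    i_peak = int(np.argmax(rates))
    mu_init = float(max(rates[i_peak], 0.05))
    # lag guess: last slow window *before* the fastest-growth window
    # (plateau windows after the rise are also slow but are not lag)
    slow = np.where(rates[: i_peak + 1] <= 0.5 * rates[i_peak])[0]
    lag_init = float(t[slow[-1]] - t[0]) if len(slow) else 1.0
    lag_init = max(lag_init, 0.1)

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        jitter = rng.lognormal(0.0, 0.3, size=2) if k else np.ones(2)
        theta0 = np.array([y0_init + (0.0 if k == 0 else rng.normal(0, 0.2)),
                           ymax_init + (0.0 if k == 0 else rng.normal(0, 0.2)),
                           np.log(mu_init * jitter[0]),
                           np.log(mu_init * lag_init * jitter[1])])
        res = optimize.minimize(
            _baranyi_objective, theta0, args=(t, y), method="Powell",
            options={"xtol": xtol, "ftol": xtol, "maxfev": 10_000})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise BaranyiFitError("Powell minimization failed for all starts")

    y0, y_max, log_mu, log_h0 = best.x
    mu, h0 = float(np.exp(log_mu)), float(np.exp(log_h0))
    mid = 0.5 * (y0 + y_max)

    def f(tt):
        return baranyi_log_counts(np.array([tt]), y0, y_max, mu, h0)[0] - mid

    t_hi = t[-1] * 5 + 10.0
    if f(t_hi) <= 0:  # fitted curve never reaches half-saturation
        t_half = float("inf")
    else:
        t_half = float(optimize.brentq(f, 0.0, t_hi))
    return AdaptationResult(
        adaptation_time=t_half, half_saturation_time=t_half, suppressed=True,
        fit_params={"y0": float(y0), "y_max": float(y_max),
                    "mu_max": mu, "h0": h0},
        fit_loss=float(best.fun),
        replicate_id=curve.replicate_id, condition=curve.condition)


def presaturation_rates(curve: GrowthCurve, window: int = 3,
                        saturation_frac: float = 0.5) -> np.ndarray:
    """Moving-window growth rates restricted to the pre-saturation segment.

    Suppression is judged on local growth rates *up to saturation*: once a
    recovered curve has reached ``saturation_frac`` of its maximum, the
    remaining windows (which flatten towards zero on the approach to the
    plateau) are excluded.  The default fraction is one half, consistent
    with the adaptation time being a half-saturation time: a population
    that was never suppressed before reaching half-saturation adapted
    immediately.  Curves that never regrew are evaluated over their whole
    length.
    """
    if has_recovered(curve):
        i_sat = int(np.argmax(curve.count >= saturation_frac * np.max(curve.count)))
        stop = max(i_sat + 1, window)
        sub = GrowthCurve(curve.t[:stop], curve.count[:stop],
                          curve.replicate_id, curve.condition)
        return moving_growth_rate(sub, window)
    return moving_growth_rate(curve, window)


def estimate_adaptation(curve: GrowthCurve, window: int = 3,
                        floor: float = EXTINCTION_FLOOR,
                        seed: int = 0) -> AdaptationResult:
    """Apply the three-way adaptation rule to a growth curve."""
    rates = presaturation_rates(curve, window)
    if not classify_suppression(rates):
        return AdaptationResult(adaptation_time=0.0, half_saturation_time=0.0,
                                suppressed=False,
                                replicate_id=curve.replicate_id,
                                condition=curve.condition)
    if is_extinct(curve, window, floor) or not has_recovered(curve):
        return AdaptationResult(adaptation_time=float("inf"),
                                half_saturation_time=float("inf"),
                                suppressed=True,
                                replicate_id=curve.replicate_id,
                                condition=curve.condition)
    return fit_baranyi(curve, window=window, seed=seed)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_adaptation(groups: Mapping[str, Sequence[AdaptationResult]],
                       alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Group means/SEMs of finite adaptation times plus pairwise rank tests.

    Infinite (non-recovering) replicates are excluded from the mean but do
    enter the Mann-Whitney ranking as largest values.  A group whose times
    are all infinite gets a NaN (flagged) mean but still participates in
    the tests.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    times = {}
    for label, results in groups.items():
        at = np.array([r.adaptation_time for r in results], dtype=float)
        times[label] = at
        finite = at[np.isfinite(at)]
        n_f = len(finite)
        rows.append({
            "group": label, "n": len(at), "n_finite": n_f,
            "n_infinite": int(np.sum(np.isinf(at))),
            "mean_adaptation_time": float(np.mean(finite)) if n_f else float("nan"),
            "sem_adaptation_time": (float(np.std(finite, ddof=1) / np.sqrt(n_f))
                                    if n_f > 1 else float("nan")),
        })
    labels = list(groups)
    pair_rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = mann_whitney(times[a], times[b])
            pair_rows.append({"group_a": a, "group_b": b, "u": res.u,
                              "p_value": res.p_value, "method": res.method,
                              "significant": res.p_value < alpha})
    return {"groups": pd.DataFrame(rows), "pairs": pd.DataFrame(pair_rows)}
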