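"""Ornstein-Uhlenbeck single-cell expression dynamics with survival.

Tests whether preexisting expression fluctuations alone can explain
observed adaptation delays.  Each cell's log expression follows a
stationary OU process, so the population law is lognormal (matching the
log-Gaussian fits used by the population model) and the mean, noise
magnitude (sd) and fluctuation relaxation/memory time (tau) are decoupled:

    x' = mu + (x - mu) e^{-dt/tau} + sd sqrt(1 - e^{-2 dt/tau}) z

the *exact* Gaussian transition, free of Euler-Maruyama step error.
Coupled to a threshold-kill rule (cells with expression below the kill
threshold die at a hazard rate; cells above divide, daughters inheriting
the mother's expression), the simulation produces populations that either
grow within days or collapse — never a multi-week flat phase followed by
fast regrowth, which is why additional cellular states (persisters,
stably resistant converts) are needed in the population model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


class MemoryFitError(RuntimeError):
    """Relaxation-time fit failed or is unidentifiable."""


@dataclass(frozen=True)
class OUParams:
    """Stationary law and memory of log expression.

    mean/sd: stationary mean and SD of *log* expression (the stationary
    expression law is lognormal); tau: relaxation (memory) time, days;
    dt: integration step, days.
    """

    mean: float
    sd: float
    tau: float
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.dt < self.tau:
            raise ValueError("require 0 < dt << tau")


@dataclass
class CellEnsemble:
    """Current log-expression state of a population of cells."""

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite expression state")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class SurvivalTrajectory:
    """Alive-cell count over time from the OU survival simulation."""

    t: np.ndarray
    n_alive: np.ndarray
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.t, "n_alive": self.n_alive})


def sample_stationary(params: OUParams, n: int,
                      rng: np.random.Generator) -> CellEnsemble:
    return CellEnsemble(rng.normal(params.mean, params.sd, size=n))


def step_ou(ensemble: CellEnsemble, params: OUParams,
            rng: np.random.Generator) -> CellEnsemble:
    """One exact OU transition of duration ``params.dt``."""
    decay = np.exp(-params.dt / params.tau)
    diff = params.sd * np.sqrt(1.0 - decay**2)
    z = rng.standard_normal(len(ensemble))
    x = params.mean + (ensemble.x - params.mean) * decay + diff * z
    return CellEnsemble(x, t=ensemble.t + params.dt)


def simulate_trajectories(params: OUParams, n_cells: int, n_steps: int,
                          seed: int = 0,
                          x0: np.ndarray | None = None) -> np.ndarray:
    """(n_steps+1, n_cells) array of log-expression paths."""
    rng = np.random.default_rng(seed)
    ens = (CellEnsemble(np.asarray(x0, dtype=float)) if x0 is not None
           else sample_stationary(params, n_cells, rng))
    out = np.empty((n_steps + 1, len(ens)))
    out[0] = ens.x
    for k in range(n_steps):
        ens = step_ou(ens, params, rng)
        out[k + 1] = ens.x
    return out


def run_survival_sim(params: OUParams, kill_threshold: float,
                     growth_rate: float, death_rate: float,
                     t_max: float, n0: int, seed: int = 0,
                     record_dt: float = 0.25,
                     cap: int = 1_000_000) -> SurvivalTrajectory:
    """Threshold-gated birth/death on top of OU expression fluctuations.

    Cells whose expression exp(x) is below ``kill_threshold`` die with
    hazard ``death_rate`` (per day); cells above divide with hazard
    ``growth_rate``, daughters inheriting the mother's expression value.
    Population exceeding ``cap`` stops the run with a truncation flag.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    ens = sample_stationary(params, n0, rng)
    dt = params.dt
    p_die = 1.0 - np.exp(-death_rate * dt)
    p_div = 1.0 - np.exp(-growth_rate * dt)
    log_thr = np.log(kill_threshold) if kill_threshold > 0 else -np.inf

    times = [0.0]
    counts = [len(ens)]
    truncated = False
    next_record = record_dt
    n_steps = int(np.ceil(t_max / dt))
    for k in range(1, n_steps + 1):
        if len(ens) == 0:
            t_now = k * dt
            while next_record <= t_max + 1e-12:
                times.append(min(next_record, t_max))
                counts.append(0)
                next_record += record_dt
            break
        ens = step_ou(ens, params, rng)
        below = ens.x < log_thr
        u = rng.random(len(ens))
        died = below & (u < p_die)
        divided = (~below) & (u < p_div)
        survivors = ens.x[~died]
        daughters = ens.x[divided & ~died]
        ens = CellEnsemble(np.concatenate([survivors, daughters]), t=ens.t)
        t_now = k * dt
        if len(ens) > cap:
            truncated = True
            times.append(t_now)
            counts.append(len(ens))
            break
        while next_record <= t_now + 1e-12:
            times.append(next_record)
            counts.append(len(ens))
            next_record += record_dt
    return SurvivalTrajectory(np.array(times), np.array(counts, dtype=float),
                              truncated=truncated)


def sorted_subpopulation_means(params: OUParams, n_cells: int,
                               sample_times: np.ndarray,
                               top_quantile: float = 0.9,
                               seed: int = 0) -> np.ndarray:
    """Mean log expression of a flow-sorted high tail relaxing back.

    Emulates the memory-estimation experiment: sort the top
    (1 - top_quantile) of a stationary ensemble, then follow the sorted
    subpopulation's mean as it relaxes to the ensemble mean.  Because the
    conditional mean of an OU process decays as e^{-t/tau}, the relaxation
    of the subpopulation mean is exactly exponential with the process tau.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    rng = np.random.default_rng(seed)
    ens = sample_stationary(params, n_cells, rng)
    cut = np.quantile(ens.x, top_quantile)
    sub = CellEnsemble(ens.x[ens.x >= cut])
    out = np.empty(len(sample_times))
    t_now = 0.0
    for i, t_target in enumerate(sample_times):
        while t_now < t_target - 1e-12:
            sub = step_ou(sub, params, rng)
            t_now += params.dt
        out[i] = float(np.mean(sub.x))
    return out


def estimate_memory(t: np.ndarray, means: np.ndarray,
                    ensemble_mean: float | None = None) -> dict:
    """Fit m(t) = m_inf + (m0 - m_inf) e^{-t/tau} to subpopulation means.

    Returns a dict with ``tau`` and the full fitted parameters.  Raises
    :class:`MemoryFitError` when the series carries no relaxation signal
    (constant within numerical noise) or the fit does not converge.
    """
    t = np.asarray(t, dtype=float)
    means = np.asarray(means, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    spread = np.max(means) - np.min(means)
    if spread < 1e-12 or spread < 1e-9 * max(1.0, abs(means[0])):
        raise MemoryFitError("constant series: relaxation time unidentifiable")

    if ensemble_mean is not None:
        def model(tt, delta, tau):
            return ensemble_mean + delta * np.exp(-tt / tau)
        p0 = [means[0] - ensemble_mean, max((t[-1] - t[0]) / 3, 1e-3)]
    else:
        def model(tt, m_inf, delta, tau):
            return m_inf + delta * np.exp(-tt / tau)
        p0 = [means[-1], means[0] - means[-1], max((t[-1] - t[0]) / 3, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(model, t, means, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        raise MemoryFitError(f"relaxation fit did not converge: {exc}") from exc
    tau = float(popt[-1])
    if tau <= 0:
        raise MemoryFitError(f"non-physical fitted tau = {tau:.3g}")
    out = {"tau": tau}
    if ensemble_mean is not None:
        out.update({"m_inf": float(ensemble_mean), "delta": float(popt[0])})
    else:
        out.update({"m_inf": float(popt[0]), "delta": float(popt[1])})
    return out
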