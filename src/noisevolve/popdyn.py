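"""Dead/persister/nongenetic/genetic-resistant population dynamics.

Partitions a clonal drug-treated population and evolves the survivors:

* the lognormal expression distribution is summarized by a Gaussian fit of
  log expression (mu, sigma);
* the initially killed fraction A_D is the Gaussian CDF of log expression
  at a kill threshold that saturates with drug dose via a
  Michaelis-Menten-type law, thres(Puro) = beta * [Puro] / (K + [Puro]);
* the persister fraction A_P follows a Gaussian-in-ln-dose curve (the
  printed form, without a 1/[Puro] Jacobian; the true lognormal pdf is
  available behind a switch for sensitivity checks), clipped into the
  surviving mass; the nongenetically resistant fraction A_N is the
  remainder, so A_D + A_P + A_N = 1 exactly;
* the P/N/G subpopulations then evolve by switching (P<->N), conversion to
  stable resistance (P->G, N->G), growth and death — deterministically
  (linear ODE) or stochastically (exact Gillespie realization).

Dead cells are removed once at t=0; there is no ongoing threshold killing
inside the dynamics.  Natural log throughout; rates are per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate as sp_integrate
from scipy.stats import norm

from .cytometry import ExpressionDistribution


class DegenerateFitError(ValueError):
    """Zero-variance sample: a lognormal fit is not identifiable."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormalFit:
    """(mu, sigma) of log expression from a Gaussian fit of log values."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))


@dataclass(frozen=True)
class KillThresholdParams:
    """Saturating dose -> kill-threshold map: beta * d / (K + d)."""

    beta: float   # maximal expression threshold (same units as expression)
    K: float      # half-saturation drug concentration, ug/mL

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.K <= 0:
            raise ValueError("beta and K must be positive")

    def threshold(self, puro: float) -> float:
        if puro < 0:
            raise ValueError("drug concentration must be non-negative")
        return self.beta * puro / (self.K + puro)


@dataclass(frozen=True)
class PersisterParams:
    """Location/scale of the persister-fraction curve in ln-dose."""

    mu_prime: float
    sigma_prime: float

    def __post_init__(self) -> None:
        if self.sigma_prime <= 0:
            raise ValueError("sigma_prime must be positive")


@dataclass(frozen=True)
class SubpopulationFractions:
    """Initial dead / persister / nongenetic-resistant partition."""

    a_d: float
    a_p: float
    a_n: float

    def __post_init__(self) -> None:
        for name, v in (("a_d", self.a_d), ("a_p", self.a_p), ("a_n", self.a_n)):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.a_d + self.a_p + self.a_n - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1 within 1e-12")

    @property
    def surviving(self) -> float:
        return self.a_p + self.a_n


@dataclass(frozen=True)
class RateSet:
    """Per-day switching, conversion, growth and death rates.

    r_pn: N->P switching; r_np: P->N switching; r_gp: P->G conversion;
    r_gn: N->G conversion; k_n/k_g: growth; g_n/g_g: death.
    """

    r_pn: float = 0.0
    r_np: float = 0.0
    r_gp: float = 0.0
    r_gn: float = 0.0
    k_n: float = 0.0
    k_g: float = 0.0
    g_n: float = 0.0
    g_g: float = 0.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"rate {name} must be non-negative")

    def matrix(self) -> np.ndarray:
        """Generator of the linear (P, N, G) system."""
        return np.array([
            [-(self.r_np + self.r_gp), self.r_pn, 0.0],
            [self.r_np, -self.r_pn - self.r_gn + self.k_n - self.g_n, 0.0],
            [self.r_gp, self.r_gn, self.k_g - self.g_g],
        ])


@dataclass
class PopulationTrajectory:
    """P/N/G subpopulation sizes over time."""

    t: np.ndarray
    p: np.ndarray
    n: np.ndarray
    g: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.g = np.asarray(self.g, dtype=float)

    @property
    def n_tot(self) -> np.ndarray:
        return self.p + self.n + self.g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "P": self.p, "N": self.n,
                             "G": self.g, "N_tot": self.n_tot})


# ---------------------------------------------------------------------------
# distribution fits and fractions
# ---------------------------------------------------------------------------

def fit_log_gaussian(dist: ExpressionDistribution | np.ndarray,
                     offset: float = 0.0) -> LogNormalFit:
    """Maximum-likelihood Gaussian fit of log-transformed expression.

    ``offset`` may shift values into positivity when the normalization
    produced small negative readings; by default values must be positive.
    """
    values = dist.values if isinstance(dist, ExpressionDistribution) else np.asarray(dist, float)
    values = values + offset
    if len(values) < 10:
        raise ValueError("need at least 10 values for a stable fit")
    if np.any(values <= 0):
        raise ValueError("values must be positive (or supply an offset)")
    logs = np.log(values)
    sigma = float(np.std(logs))
    if sigma < 1e-12:
        raise DegenerateFitError("constant sample: sigma would be 0")
    return LogNormalFit(mu=float(np.mean(logs)), sigma=sigma)


def killed_fraction(fit: LogNormalFit, thresh: KillThresholdParams,
                    puro: float) -> float:
    """A_D: lognormal mass below the dose-dependent kill threshold.

    A_D = Phi((ln thres - mu) / sigma); the thres -> 0 limit (zero dose)
    gives A_D = 0 so the whole population initially survives.
    """
    thr = thresh.threshold(puro)
    if thr <= 0:
        return 0.0
    return float(norm.cdf((np.log(thr) - fit.mu) / fit.sigma))


def persister_fraction(params: PersisterParams, puro: float,
                       jacobian: bool = False) -> float:
    """A_P: Gaussian-in-ln-dose persister induction curve.

    Evaluates the curve exactly as a Gaussian density in ln(dose); with
    ``jacobian=True`` the true lognormal pdf (extra 1/dose factor) is used
    instead, as a sensitivity variant.  Zero dose gives A_P = 0 by
    convention.  The raw value is a curve amplitude, not yet constrained
    to the surviving mass — composition happens in
    :func:`initial_fractions`.
    """
    if puro < 0:
        raise ValueError("drug concentration must be non-negative")
    if puro == 0:
        return 0.0
    z = (np.log(puro) - params.mu_prime) / params.sigma_prime
    val = np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * params.sigma_prime)
    if jacobian:
        val /= puro
    return float(val)


def initial_fractions(fit: LogNormalFit, thresh: KillThresholdParams,
                      pers: PersisterParams, puro: float,
                      jacobian: bool = False) -> SubpopulationFractions:
    """Compose A_D, A_P, A_N with A_D + A_P + A_N = 1.

    The persister curve value is read as a fraction of the total initial
    population and clipped into the surviving mass (with a warning when
    clipping bites): a_p = min(A_P_raw, 1 - a_d), a_n = remainder.  At very
    high dose a_d -> 1 and every surviving cell is a persister.
    """
    a_d = killed_fraction(fit, thresh, puro)
    raw_ap = persister_fraction(pers, puro, jacobian=jacobian)
    surviving = 1.0 - a_d
    if raw_ap > surviving:
        warnings.warn(
            f"persister curve value {raw_ap:.3g} exceeds surviving mass "
            f"{surviving:.3g}; clipping", UserWarning, stacklevel=2)
        a_p = surviving
    else:
        a_p = raw_ap
    a_n = 1.0 - a_d - a_p
    # guard against floating-point drift breaking the exact-sum invariant
    a_n = max(a_n, 0.0)
    a_d = 1.0 - a_p - a_n
    return SubpopulationFractions(a_d=a_d, a_p=a_p, a_n=a_n)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _initial_counts(fracs: SubpopulationFractions, n0: float) -> np.ndarray:
    """(P0, N0, G0) after removing the dead fraction at t=0."""
    return np.array([fracs.a_p * n0, fracs.a_n * n0, 0.0])


def _birth_rates(rates: RateSet, n_tot: float,
                 capacity: float | None) -> tuple[float, float]:
    """Per-cell birth rates of N and G, capacity-damped on the net excess."""
    if capacity is None:
        return rates.k_n, rates.k_g
    damp = max(0.0, 1.0 - n_tot / capacity)
    b_n = min(rates.k_n, rates.g_n + (rates.k_n - rates.g_n) * damp)
    b_g = min(rates.k_g, rates.g_g + (rates.k_g - rates.g_g) * damp)
    return b_n, b_g


def integrate_ode(fracs: SubpopulationFractions, rates: RateSet, n0: float,
                  t_max: float, dt: float = 0.1,
                  capacity: float | None = None) -> PopulationTrajectory:
    """Deterministic integration of the P/N/G system.

    Without a capacity the system is linear (dY/dt = M Y).  With
    ``capacity`` the *net* growth excess is damped logistically — the
    per-cell birth rate becomes min(k, g + (k - g)(1 - N_tot/capacity)) —
    so every net-growing subpopulation saturates at the same confluency
    level (no damping applies to net-shrinking subpopulations).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    y0 = _initial_counts(fracs, n0)
    t_eval = np.arange(0.0, t_max + dt / 2, dt)

    def rhs(_t, y):
        p, n, g = y
        b_n, b_g = _birth_rates(rates, p + n + g, capacity)
        dp = rates.r_pn * n - (rates.r_np + rates.r_gp) * p
        dn = (rates.r_np * p - rates.r_pn * n - rates.r_gn * n
              + b_n * n - rates.g_n * n)
        dg = (rates.r_gp * p + rates.r_gn * n + b_g * g - rates.g_g * g)
        return [dp, dn, dg]

    sol = sp_integrate.solve_ivp(rhs, (0.0, t_max), y0, t_eval=t_eval,
                                 method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    p, n, g = np.clip(sol.y, 0.0, None)
    return PopulationTrajectory(sol.t, p, n, g)


# state-change vectors of the 8 reaction channels, order matching _propensities
_STOICH = np.array([
    [+1, -1, 0],   # N -> P
    [-1, +1, 0],   # P -> N
    [-1, 0, +1],   # P -> G
    [0, -1, +1],   # N -> G
    [0, +1, 0],    # N -> 2N
    [0, 0, +1],    # G -> 2G
    [0, -1, 0],    # N -> 0
    [0, 0, -1],    # G -> 0
])


def _propensities(p: float, n: float, g: float, rates: RateSet,
                  capacity: float | None) -> np.ndarray:
    b_n, b_g = _birth_rates(rates, p + n + g, capacity)
    return np.array([rates.r_pn * n, rates.r_np * p, rates.r_gp * p,
                     rates.r_gn * n, b_n * n, b_g * g,
                     rates.g_n * n, rates.g_g * g])


def simulate_stochastic(fracs: SubpopulationFractions, rates: RateSet,
                        n0: float, t_max: float, seed: int = 0,
                        record_dt: float = 1.0,
                        capacity: float | None = None,
                        cap: float = 5e6,
                        leap_threshold: float = 1000.0) -> PopulationTrajectory:
    """Stochastic realization of the switching/conversion network.

    Exact Gillespie simulation with the rate terms of the deterministic
    system as propensities: N->P, P->N, P->G, N->G, N and G birth
    (capacity-damped) and N and G death.  For large populations (total
    propensity over a recording interval above ``leap_threshold`` events
    and at least 2000 cells) the simulator switches to tau-leaping with
    steps sized for ~2% relative population change, which is statistically
    indistinguishable at those sizes but orders of magnitude faster;
    ``leap_threshold=inf`` forces the exact algorithm throughout.  The
    trajectory is recorded on a uniform grid.  Exceeding ``cap`` cells
    stops the run with a truncation flag.
    """
    if n0 < 1:
        raise ValueError("n0 must be at least 1")
    rng = np.random.default_rng(seed)
    p, n, g = (int(round(v)) for v in _initial_counts(fracs, n0))
    t = 0.0
    grid = np.arange(0.0, t_max + record_dt / 2, record_dt)
    out = np.zeros((len(grid), 3))
    idx = 0
    truncated = False

    while True:
        tot = p + n + g
        props = _propensities(p, n, g, rates, capacity)
        total_rate = props.sum()

        use_leap = (total_rate * record_dt > leap_threshold and tot > 2000)
        if use_leap:
            tau = min(max(0.02 * tot, 20.0) / total_rate, record_dt,
                      t_max - t + 1e-9)
            state = np.array([p, n, g])
            for _ in range(6):  # shrink tau if a draw overshoots a count
                k = rng.poisson(props * tau)
                new = state + _STOICH.T @ k
                if np.all(new >= 0):
                    break
                tau /= 2
            else:
                new = np.clip(new, 0, None)
            t_new = t + tau
            while idx < len(grid) and grid[idx] <= t + 1e-12:
                out[idx] = state
                idx += 1
            p, n, g = (int(v) for v in new)
            t = t_new
            if t >= t_max - 1e-12:
                break
            if p + n + g > cap:
                truncated = True
                break
            continue

        t_next = t + (rng.exponential(1.0 / total_rate) if total_rate > 0
                      else np.inf)
        while idx < len(grid) and grid[idx] <= min(t_next, t_max) + 1e-12:
            out[idx] = (p, n, g)
            idx += 1
        if t_next > t_max:
            break
        t = t_next
        c = np.searchsorted(np.cumsum(props), rng.random() * total_rate,
                            side="right")
        dp, dn, dg = _STOICH[c]
        p += dp; n += dn; g += dg
        if p + n + g > cap:
            truncated = True
            break
    # fill any trailing grid points (population state persists)
    while idx < len(grid):
        out[idx] = (p, n, g)
        idx += 1
    return PopulationTrajectory(grid, out[:, 0], out[:, 1], out[:, 2],
                                truncated=truncated)


# ---------------------------------------------------------------------------
# rate scanning
# ---------------------------------------------------------------------------

def classify_trajectory(traj: PopulationTrajectory, window: int = 3,
                        floor: float = 1.0) -> str:
    """Immediate growth / delayed adaptation / extinction / no recovery."""
    from .adaptation import (GrowthCurve, classify_suppression, has_recovered,
                             is_extinct, presaturation_rates)
    curve = GrowthCurve(traj.t, np.clip(traj.n_tot, 0.0, None))
    rates = presaturation_rates(curve, window)
    if not classify_suppression(rates):
        return "immediate_growth"
    if is_extinct(curve, window, floor):
        return "extinction"
    if has_recovered(curve):
        return "delayed_adaptation"
    return "no_recovery"


def scan_rates(base: RateSet, fracs_by_dose: dict[float, SubpopulationFractions],
               span_decades: int = 4, points_per_decade: int = 1,
               scanned: tuple[str, ...] = ("r_pn", "r_np", "r_gp", "r_gn"),
               n0: float = 2000.0, t_max: float = 30.0,
               capacity: float | None = 20_000.0,
               include_zero: bool = True) -> pd.DataFrame:
    """Grid scan of switching/conversion rates across doses.

    Each scanned rate is varied over ``span_decades`` orders of magnitude
    around its base value (optionally including 0, which exposes the
    no-P->G-conversion family); every combination is run deterministically
    at every dose and classified.  The ``r_gp_zero`` column flags the
    sub-family without persister-to-stable-resistant conversion.
    """
    if span_decades < 1:
        raise ValueError("span_decades must be at least 1")
    n_pts = span_decades * points_per_decade + 1
    exponents = np.linspace(-span_decades / 2, span_decades / 2, n_pts)

    def levels(rate_val: float) -> np.ndarray:
        vals = rate_val * 10.0**exponents if rate_val > 0 else np.zeros(1)
        if include_zero:
            vals = np.concatenate([[0.0], vals])
        return np.unique(vals)

    grids = [levels(getattr(base, r)) for r in scanned]
    rows = []
    mesh = np.meshgrid(*grids, indexing="ij")
    combos = np.stack([m.ravel() for m in mesh], axis=1)
    for combo in combos:
        kw = {k: float(v) for k, v in zip(scanned, combo)}
        rates = RateSet(**{**vars(base), **kw})
        for dose, fracs in fracs_by_dose.items():
            traj = integrate_ode(fracs, rates, n0, t_max, dt=0.5,
                                 capacity=capacity)
            cls = classify_trajectory(traj)
            rows.append({**kw, "dose": dose, "class": cls,
                         "r_gp_zero": kw.get("r_gp", base.r_gp) == 0.0,
                         "final_n_tot": float(traj.n_tot[-1])})
    return pd.DataFrame(rows)
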