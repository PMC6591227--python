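"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every input the pipeline consumes, so the full analysis is
testable without instrument data:

* cytometry event tables — lognormal single-cell EGFP intensities for a
  broad high-noise (mPF) or narrow low-noise (mNF) circuit on top of an
  autofluorescence background, a small silenced/basal subpopulation below
  the fluorescence cutoff, a bivariate-lognormal scatter cloud of intact
  cells plus a diffuse low-scatter debris cloud (so density gating has
  something to remove);
* an 8-peak calibration-bead sample for the normalization denominator;
* inducer (Doxycycline) dose-response panels: sigmoidal mean response for
  the positive-feedback circuit, linear-then-saturating for the negative-
  feedback circuit, with noise peaking at intermediate induction for mPF;
* three-phase growth curves (suppression, regrowth, saturation) with known
  ground-truth timings for recovery tests.

All intensities are in linear arbitrary units >= 0; time is in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adaptation import GrowthCurve
from .cytometry import EventTable

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircuitSpec:
    """Lognormal expression model of one noise-controlling circuit.

    ``mean_log``/``sd_log`` are the location and scale of log raw
    fluorescence; ``relaxation_time`` is the expression-memory timescale in
    days (used by the OU module); ``basal_fraction`` is the share of events
    in the silenced/non-expressing low peak that the fluorescence cutoff is
    meant to remove.
    """

    name: str
    mean_log: float
    sd_log: float
    relaxation_time: float
    basal_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_log <= 0:
            raise ValueError("sd_log must be positive")
        if self.relaxation_time <= 0:
            raise ValueError("relaxation_time must be positive")
        if not 0 <= self.basal_fraction < 1:
            raise ValueError("basal_fraction must be in [0, 1)")

    @property
    def linear_mean(self) -> float:
        """Back-transformed mean of the expressing component."""
        return float(np.exp(self.mean_log + self.sd_log**2 / 2))

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        return cls(**d)


# Default decoupled-noise-point pair: matched back-transformed means
# (~5.0e4 a.u.), high vs low log-scale SD, long vs short memory.
MPF = CircuitSpec("mPF", mean_log=np.log(5.0e4) - 0.9**2 / 2, sd_log=0.9,
                  relaxation_time=2.0, basal_fraction=0.03)
MNF = CircuitSpec("mNF", mean_log=np.log(5.0e4) - 0.3**2 / 2, sd_log=0.3,
                  relaxation_time=0.5, basal_fraction=0.03)


@dataclass(frozen=True)
class BeadSpec:
    """Multi-peak calibration-bead intensity ladder."""

    peak_means: tuple = tuple(np.geomspace(150.0, 2.5e5, 8))
    peak_cv: float = 0.04

    def __post_init__(self) -> None:
        means = np.asarray(self.peak_means, dtype=float)
        if means.size == 0:
            raise ValueError("peak_means must be non-empty")
        if np.any(np.diff(means) <= 0):
            raise ValueError("peak_means must be strictly increasing")
        if self.peak_cv < 0:
            raise ValueError("peak_cv must be non-negative")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_means)


@dataclass(frozen=True)
class GrowthCurveSpec:
    """Piecewise three-phase growth model: flat, exponential, saturated."""

    suppression_duration: float = 8.0   # days
    regrowth_rate: float = 0.7          # 1/day
    saturation_count: float = 20_000.0
    initial_count: float = 500.0
    sampling_interval: float = 1.0      # days
    noise_cv: float = 0.1               # multiplicative count noise
    duration: float | None = None       # auto: suppression + rise + margin

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.initial_count < 0 or self.saturation_count <= self.initial_count:
            raise ValueError("require saturation_count > initial_count >= 0")
        if self.regrowth_rate < 0:
            raise ValueError("regrowth_rate must be non-negative "
                             "(declines are modeled elsewhere)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def _scatter_channels(rng: np.random.Generator, n: int,
                      debris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cells: correlated bivariate lognormal cloud; debris: diffuse low cloud."""
    cov = np.array([[0.010, 0.006], [0.006, 0.014]])
    cells = rng.multivariate_normal([5.0, 4.5], cov, size=n)  # log10 units
    fsc = 10 ** cells[:, 0]
    ssc = 10 ** cells[:, 1]
    nd = int(debris.sum())
    fsc[debris] = 10 ** rng.uniform(2.0, 4.2, size=nd)
    ssc[debris] = 10 ** rng.uniform(2.0, 4.0, size=nd)
    return fsc, ssc


def simulate_events(circuit: CircuitSpec, n_events: int,
                    autofluor_mean: float = 150.0,
                    autofluor_sd: float = 40.0,
                    debris_fraction: float = 0.05,
                    seed: int = 0) -> EventTable:
    """Draw one cytometry sample for a circuit at fixed induction.

    Fluorescence per event = autofluorescence draw + (unless the event is
    silenced/basal or debris) a lognormal circuit draw.  Per-event labels
    (``component``: circuit/basal/debris) are recorded in the metadata for
    gate and filter validation.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    rng = np.random.default_rng(seed)
    debris = rng.random(n_events) < debris_fraction
    basal = (~debris) & (rng.random(n_events) < circuit.basal_fraction)
    expressing = ~(debris | basal)

    fl1 = rng.normal(autofluor_mean, autofluor_sd, size=n_events)
    circuit_level = np.zeros(n_events)
    circuit_level[expressing] = rng.lognormal(
        circuit.mean_log, circuit.sd_log, size=int(expressing.sum()))
    fl1 = np.clip(fl1 + circuit_level, 0.0, None)

    fsc, ssc = _scatter_channels(rng, n_events, debris)
    component = np.where(debris, "debris", np.where(basal, "basal", "circuit"))
    meta = pd.DataFrame({"component": component,
                         "circuit_level": circuit_level})
    return EventTable(fsc, ssc, fl1, sample_id=circuit.name, metadata=meta)


def simulate_beads(spec: BeadSpec = BeadSpec(), n_events: int = 8000,
                   seed: int = 0) -> EventTable:
    """Calibration-bead sample: a mixture of tight intensity clusters.

    Cluster assignments are stored in the metadata (``peak`` column) for
    test introspection of the peak detector.
    """
    if n_events < spec.n_peaks:
        raise ValueError("need at least one event per peak")
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, spec.n_peaks, size=n_events)
    means = np.asarray(spec.peak_means, dtype=float)[assign]
    fl1 = np.clip(rng.normal(means, spec.peak_cv * means), 0.0, None)
    # beads are monodisperse: one tight scatter cluster
    fsc = 10 ** rng.normal(4.8, 0.05, size=n_events)
    ssc = 10 ** rng.normal(4.6, 0.05, size=n_events)
    meta = pd.DataFrame({"peak": assign})
    return EventTable(fsc, ssc, fl1, sample_id="beads", metadata=meta)


def simulate_parental(n_events: int = 8000, autofluor_mean: float = 150.0,
                      autofluor_sd: float = 40.0, debris_fraction: float = 0.05,
                      seed: int = 0) -> EventTable:
    """Circuit-free parental line: pure autofluorescence reference."""
    blank = CircuitSpec("parental", mean_log=0.0, sd_log=1e-9,
                        relaxation_time=1.0, basal_fraction=0.999999)
    table = simulate_events(blank, n_events, autofluor_mean, autofluor_sd,
                            debris_fraction, seed)
    table.sample_id = "parental"
    return table


# ---------------------------------------------------------------------------
# dose-response panels
# ---------------------------------------------------------------------------

def circuit_at_dose(base: CircuitSpec, dox: float) -> CircuitSpec:
    """Induction-dependent circuit spec for a Doxycycline concentration.

    mPF: sigmoidal (Hill, steep) mean response with noise maximal at
    intermediate induction, the signature of positive feedback.  mNF:
    linear-then-saturating mean response with uniformly low noise.  The
    parameterization is a free modeling choice calibrated so the two
    default circuits reach matching means at their decoupling doses
    (mNF ~0.05, mPF ~6 ng/mL).
    """
    if dox < 0:
        raise ValueError("dox must be non-negative")
    if base.name.lower().startswith("mpf"):
        ec50, hill = 5.0, 4.0
        frac = dox**hill / (ec50**hill + dox**hill) if dox > 0 else 0.0
        m_min, m_max = 600.0, 7.3e4
        sd = 0.25 + 0.65 * 4.0 * frac * (1.0 - frac) + (0.9 - 0.82) * frac
    else:
        km = 0.2
        frac = dox / (km + dox) if dox > 0 else 0.0
        m_min, m_max = 500.0, 2.48e5
        sd = base.sd_log
    mean_lin = m_min + (m_max - m_min) * frac
    return replace(base, mean_log=float(np.log(mean_lin) - sd**2 / 2),
                   sd_log=float(sd))


DEFAULT_DOX_PANEL_MPF = (0.0, 1.0, 2.0, 4.0, 6.0, 10.0, 20.0, 50.0)
DEFAULT_DOX_PANEL_MNF = (0.0, 0.01, 0.03, 0.05, 0.1, 0.3, 1.0, 5.0)


def simulate_dose_response(base: CircuitSpec, doses, n_events: int = 5000,
                           n_replicates: int = 3, seed: int = 0
                           ) -> list[tuple[float, list[EventTable]]]:
    """Replicated event tables across an inducer dose panel."""
    out = []
    ss = np.random.SeedSequence(seed)
    for dose in doses:
        spec = circuit_at_dose(base, dose)
        reps = []
        for _ in range(n_replicates):
            child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            reps.append(simulate_events(spec, n_events, seed=child))
        out.append((float(dose), reps))
    return out


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def growth_curve_closed_form(spec: GrowthCurveSpec, t: np.ndarray) -> np.ndarray:
    """Noiseless three-phase curve: flat, exponential, clipped at saturation."""
    t = np.asarray(t, dtype=float)
    grown = spec.initial_count * np.exp(
        spec.regrowth_rate * np.clip(t - spec.suppression_duration, 0.0, None))
    return np.minimum(grown, spec.saturation_count)


def half_saturation_times(spec: GrowthCurveSpec) -> dict[str, float]:
    """Ground-truth crossing times of the noiseless curve.

    ``linear``: count = saturation/2; ``log``: count = geometric mean of
    initial and saturation counts (the log-scale midpoint the Baranyi-based
    adaptation time estimates).  Infinite when the curve cannot rise.
    """
    if spec.regrowth_rate == 0:
        return {"linear": float("inf"), "log": float("inf")}
    r, s = spec.regrowth_rate, spec.suppression_duration
    lin = s + np.log(spec.saturation_count / 2 / spec.initial_count) / r
    log_mid = s + np.log(np.sqrt(spec.saturation_count / spec.initial_count)) / r
    return {"linear": float(max(lin, 0.0)), "log": float(max(log_mid, 0.0))}


def simulate_growth_curve(spec: GrowthCurveSpec, seed: int = 0,
                          replicate_id: str = "r1",
                          condition: str = "") -> GrowthCurve:
    """Sample a three-phase growth curve with multiplicative count noise.

    The noise factor is lognormal with unit mean and CV ``spec.noise_cv``
    (zero gives the exact closed form).  Ground-truth half-saturation times
    are attached for recovery tests.
    """
    rng = np.random.default_rng(seed)
    if spec.duration is not None:
        duration = spec.duration
    else:
        rise = (np.log(spec.saturation_count / max(spec.initial_count, 1.0))
                / spec.regrowth_rate if spec.regrowth_rate > 0 else 10.0)
        duration = spec.suppression_duration + rise + 5 * spec.sampling_interval
    t = np.arange(0.0, duration + 0.5 * spec.sampling_interval,
                  spec.sampling_interval)
    clean = growth_curve_closed_form(spec, t)
    if spec.noise_cv > 0:
        s = np.sqrt(np.log1p(spec.noise_cv**2))
        factor = rng.lognormal(-s**2 / 2, s, size=len(t))
        count = clean * factor
    else:
        count = clean
    gt = dict(half_saturation_times(spec))
    gt["spec"] = spec
    return GrowthCurve(t, count, replicate_id=replicate_id,
                       condition=condition, ground_truth=gt)
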