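"""Flow-cytometry event processing and noise-vs-mean analysis.

Implements the measurement side of noise-mean decoupling between a
high-noise positive-feedback (mPF) and a low-noise negative-feedback (mNF)
reporter circuit:

* adaptive density gating of (log FSC, log SSC) scatter to exclude debris,
* a hard fluorescence cutoff (default 2000 a.u., strict ``>``) separating
  non-expressing/silenced events from cells with an active circuit,
* normalization of each event: (FL1 - autofluorescence mean) / mean of the
  brightest calibration-bead peak,
* population mean and noise amplitude CV = sigma/mu, with the population
  (1/N) variance convention,
* noise-mean curves over an inducer (Doxycycline) dose panel, and detection
  of decoupled noise points (DNPs): dose pairs with means differing by less
  than a tolerance (default 10%) but significantly different replicate CVs
  under the two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from ._stats import mann_whitney, require_feasible

DEFAULT_CUTOFF = 2000.0
DEFAULT_EVENT_CAP = 20_000


class EmptyGateError(ValueError):
    """Density gate retained no events."""


class PeakDetectionError(ValueError):
    """Fewer bead-intensity peaks detected than expected."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Per-cell scatter and fluorescence readings for one cytometry sample.

    ``metadata`` optionally carries per-event ground-truth labels from the
    synthetic generator (component, debris flag, bead peak index) so gates
    and filters can be validated against known cluster membership.
    """

    fsc: np.ndarray
    ssc: np.ndarray
    fl1: np.ndarray
    sample_id: str = ""
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.fl1 = np.asarray(self.fl1, dtype=float)
        if not (len(self.fsc) == len(self.ssc) == len(self.fl1)):
            raise ValueError("FSC, SSC and FL1 must have equal length")
        for name, ch in (("FSC", self.fsc), ("SSC", self.ssc), ("FL1", self.fl1)):
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"non-finite intensities in channel {name}")
        if self.metadata is not None and len(self.metadata) != len(self.fsc):
            raise ValueError("metadata must have one row per event")

    def __len__(self) -> int:
        return len(self.fl1)

    def subset(self, mask: np.ndarray) -> "EventTable":
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[np.asarray(mask)].reset_index(drop=True)
        return EventTable(self.fsc[mask], self.ssc[mask], self.fl1[mask],
                          self.sample_id, meta)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"FSC": self.fsc, "SSC": self.ssc, "FL1": self.fl1})
        if self.metadata is not None:
            df = pd.concat([df, self.metadata.reset_index(drop=True)], axis=1)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str = "") -> "EventTable":
        extra = [c for c in df.columns if c not in ("FSC", "SSC", "FL1")]
        meta = df[extra].reset_index(drop=True) if extra else None
        return cls(df["FSC"].to_numpy(), df["SSC"].to_numpy(),
                   df["FL1"].to_numpy(), sample_id, meta)

    @classmethod
    def read_csv(cls, path, sample_id: str = "") -> "EventTable":
        return cls.from_frame(pd.read_csv(path), sample_id=sample_id)


@dataclass(frozen=True)
class NormalizationControls:
    """Technical-variation controls entering the normalization formula."""

    egfp_auto: float          # mean autofluorescence of the parental line
    egfp_max: float           # mean of the brightest calibration-bead peak
    egfp_cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.egfp_max <= 0:
            raise ValueError("egfp_max must be positive")
        if self.egfp_cutoff <= self.egfp_auto:
            raise ValueError("cutoff must exceed the autofluorescence mean")


@dataclass
class ExpressionDistribution:
    """Normalized per-cell expression values with summary statistics.

    Mean is the arithmetic mean of the normalized values and the variance
    uses the population convention sigma^2 = <x^2> - <x>^2.  CV is NaN
    (flagged) when the mean is not positive.
    """

    values: np.ndarray
    sample_id: str = ""
    n: int = field(init=False)
    mean: float = field(init=False)
    cv: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n = len(self.values)
        if self.n == 0:
            self.mean = float("nan")
            self.cv = float("nan")
            return
        self.mean = float(np.mean(self.values))
        var = float(np.mean(self.values**2) - self.mean**2)
        sigma = np.sqrt(max(var, 0.0))
        self.cv = sigma / self.mean if self.mean > 0 else float("nan")

    @property
    def flagged(self) -> bool:
        return not np.isfinite(self.cv)


@dataclass
class NoiseMeanCurve:
    """Noise (CV) as a function of normalized mean over an inducer panel.

    ``points`` has one row per dose with replicate-averaged mean and CV and
    their standard errors; ``replicates`` retains the per-replicate values
    needed for the rank test at decoupled noise points.
    """

    points: pd.DataFrame
    replicates: dict[float, tuple[np.ndarray, np.ndarray]]
    label: str = ""


@dataclass(frozen=True)
class DecoupledNoisePoint:
    dose_a: float
    dose_b: float
    mean_a: float
    mean_b: float
    cv_a: float
    cv_b: float
    mean_rel_diff: float
    p_value: float
    regime: str  # "low" / "high" / "unresolved" relative to curve crossing


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def gate_events(table: EventTable, density_quantile: float,
                bins: int = 64, smooth_sigma: float = 1.5,
                max_events: int | None = DEFAULT_EVENT_CAP,
                full_output: bool = False):
    """Adaptive density gate on (log10 FSC, log10 SSC).

    A 2-D histogram of log-transformed scatter is smoothed with a Gaussian
    kernel; each event is assigned the density of its bin and events whose
    density falls below the ``density_quantile`` quantile are discarded as
    debris.  ``density_quantile=0`` retains everything.  After gating, at
    most ``max_events`` events are kept (instrument-style cap).
    """
    if len(table) < 50:
        raise ValueError("need at least 50 events to estimate a density gate")
    if not 0 <= density_quantile < 1:
        raise ValueError("density_quantile must be in [0, 1)")
    lf = np.log10(np.clip(table.fsc, 1e-6, None))
    ls = np.log10(np.clip(table.ssc, 1e-6, None))
    hist, xe, ye = np.histogram2d(lf, ls, bins=bins)
    dens = ndimage.gaussian_filter(hist, smooth_sigma)
    ix = np.clip(np.searchsorted(xe, lf, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, ls, side="right") - 1, 0, bins - 1)
    d = dens[ix, iy]
    thr = np.quantile(d, density_quantile)
    mask = d >= thr
    if not mask.any():
        raise EmptyGateError("all events fell below the density threshold")
    gated = table.subset(mask)
    retained = len(gated) / len(table)
    if max_events is not None and len(gated) > max_events:
        gated = gated.subset(np.arange(len(gated)) < max_events)
    if full_output:
        return gated, {"retained_fraction": retained, "threshold": float(thr)}
    return gated


def filter_fluorescence(table: EventTable,
                        cutoff: float = DEFAULT_CUTOFF) -> EventTable:
    """Keep events with FL1 strictly above ``cutoff`` (ties excluded).

    The cutoff removes non-fluorescent and silenced-circuit events before
    normalization; an empty result is allowed (downstream flags it).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return table.subset(table.fl1 > cutoff)


def normalize(table: EventTable,
              controls: NormalizationControls) -> ExpressionDistribution:
    """Per-event normalization (FL1 - EGFP_auto) / EGFP_max.

    Negative normalized values (events dimmer than the autofluorescence
    mean after filtering) are retained, not clipped.
    """
    values = (table.fl1 - controls.egfp_auto) / controls.egfp_max
    return ExpressionDistribution(values, sample_id=table.sample_id)


def detect_bead_peaks(beads: EventTable, bin_width: float = 0.02,
                      smooth_sigma: float = 2.0,
                      min_prominence_frac: float = 0.05) -> np.ndarray:
    """Locate calibration-bead intensity peaks by 1-D mode detection.

    Works on log10 intensity: a smoothed histogram (fixed resolution of
    ``bin_width`` dex so a narrow single-peak sample is not shattered
    into spurious modes) is scanned for local maxima, events are assigned
    to the nearest detected mode, and the arithmetic mean intensity of
    each cluster is returned in increasing order.
    """
    if len(beads) == 0:
        raise ValueError("empty bead table")
    li = np.log10(np.clip(beads.fl1, 1e-6, None))
    lo, hi = li.min() - 5 * bin_width, li.max() + 5 * bin_width
    n_bins = int(np.clip(np.ceil((hi - lo) / bin_width), 16, 1024))
    hist, edges = np.histogram(li, bins=n_bins, range=(lo, hi))
    smooth = ndimage.gaussian_filter1d(hist.astype(float), smooth_sigma)
    peaks, _ = signal.find_peaks(smooth, prominence=min_prominence_frac * smooth.max())
    if len(peaks) == 0:
        raise PeakDetectionError("no bead peaks detected")
    centers = 0.5 * (edges[:-1] + edges[1:])[peaks]
    assign = np.argmin(np.abs(li[:, None] - centers[None, :]), axis=1)
    means = np.array([beads.fl1[assign == k].mean() for k in range(len(centers))])
    return np.sort(means)


def estimate_controls(parental: EventTable, beads: EventTable,
                      cutoff: float = DEFAULT_CUTOFF,
                      expected_peaks: int | None = 8,
                      density_quantile: float = 0.05) -> NormalizationControls:
    """Derive normalization controls from the two reference samples.

    EGFP_auto is the mean FL1 of the gated parental (circuit-free) line;
    EGFP_max the mean of the brightest bead peak.  Warns when the cutoff is
    not at least three autofluorescence SDs above the autofluorescence mean,
    the stated justification for the fixed threshold.
    """
    if len(parental) == 0 or len(beads) == 0:
        raise ValueError("parental and bead tables must be non-empty")
    gated = gate_events(parental, density_quantile) if len(parental) >= 50 else parental
    auto_mean = float(np.mean(gated.fl1))
    auto_sd = float(np.std(gated.fl1))
    peak_means = detect_bead_peaks(beads)
    if expected_peaks is not None and len(peak_means) < expected_peaks:
        raise PeakDetectionError(
            f"detected {len(peak_means)} bead peaks, expected {expected_peaks}")
    if cutoff < auto_mean + 3 * auto_sd:
        warnings.warn(
            f"cutoff {cutoff:.0f} is below autofluorescence mean + 3 SD "
            f"({auto_mean + 3 * auto_sd:.0f}); silenced events may leak through",
            UserWarning, stacklevel=2)
    return NormalizationControls(egfp_auto=auto_mean,
                                 egfp_max=float(peak_means[-1]),
                                 egfp_cutoff=cutoff)


def build_noise_mean_curve(
        samples: Sequence[tuple[float, Sequence[ExpressionDistribution]]],
        label: str = "") -> NoiseMeanCurve:
    """Replicate-averaged mean and CV per inducer dose, with SEMs.

    SEM is sample SD / sqrt(n) over replicates; with a single replicate it
    is reported as NaN (flagged), never silently zero.
    """
    rows = []
    reps: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for dose, dists in samples:
        if len(dists) < 1:
            raise ValueError(f"dose {dose}: at least one replicate required")
        means = np.array([d.mean for d in dists])
        cvs = np.array([d.cv for d in dists])
        n = len(dists)
        sem = (lambda a: float(np.std(a, ddof=1) / np.sqrt(n)) if n > 1
               else float("nan"))
        rows.append({"dose": dose, "mean": float(np.mean(means)),
                     "cv": float(np.mean(cvs)), "sem_mean": sem(means),
                     "sem_cv": sem(cvs), "n_replicates": n})
        reps[dose] = (means, cvs)
    points = pd.DataFrame(rows).sort_values("dose").reset_index(drop=True)
    return NoiseMeanCurve(points=points, replicates=reps, label=label)


def _crossing_mean(curve_a: NoiseMeanCurve, curve_b: NoiseMeanCurve) -> float | None:
    """Mean-expression value where the two CV-vs-mean curves intersect."""
    a, b = curve_a.points, curve_b.points
    lo = max(a["mean"].min(), b["mean"].min())
    hi = min(a["mean"].max(), b["mean"].max())
    if not lo < hi:
        return None
    grid = np.linspace(lo, hi, 256)
    fa = np.interp(grid, a["mean"].to_numpy(), a["cv"].to_numpy())
    fb = np.interp(grid, b["mean"].to_numpy(), b["cv"].to_numpy())
    diff = fa - fb
    sign = np.sign(diff)
    flips = np.where(np.diff(sign) != 0)[0]
    if len(flips) == 0:
        return None
    i = flips[0]
    # linear interpolation of the zero crossing
    x0, x1, d0, d1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
    return float(x0 - d0 * (x1 - x0) / (d1 - d0)) if d1 != d0 else float(x0)


def find_decoupled_points(curve_a: NoiseMeanCurve, curve_b: NoiseMeanCurve,
                          mean_tol: float = 0.10,
                          alpha: float = 0.05) -> list[DecoupledNoisePoint]:
    """Dose pairs where means match within ``mean_tol`` but CVs differ.

    Mean matching: |mean_a - mean_b| / max(mean_a, mean_b) < mean_tol.
    Noise difference: two-sided Mann-Whitney U on replicate CVs, p < alpha.
    Each accepted pair is labelled with the noise regime ("low"/"high")
    relative to the mean at which the two noise-mean curves cross.
    """
    boundary = _crossing_mean(curve_a, curve_b)
    out: list[DecoupledNoisePoint] = []
    for _, ra in curve_a.points.iterrows():
        for _, rb in curve_b.points.iterrows():
            ma, mb = ra["mean"], rb["mean"]
            denom = max(ma, mb)
            if denom <= 0:
                continue
            rel = abs(ma - mb) / denom
            if rel >= mean_tol:
                continue
            cva = curve_a.replicates[ra["dose"]][1]
            cvb = curve_b.replicates[rb["dose"]][1]
            require_feasible(len(cva), len(cvb), alpha)
            res = mann_whitney(cva, cvb)
            if res.p_value >= alpha:
                continue
            mid = 0.5 * (ma + mb)
            if boundary is None:
                regime = "unresolved"
            else:
                regime = "low" if mid < boundary else "high"
            out.append(DecoupledNoisePoint(
                dose_a=float(ra["dose"]), dose_b=float(rb["dose"]),
                mean_a=float(ma), mean_b=float(mb),
                cv_a=float(ra["cv"]), cv_b=float(rb["cv"]),
                mean_rel_diff=float(rel), p_value=res.p_value, regime=regime))
    return out


def summaries_to_frame(dists: Sequence[ExpressionDistribution]) -> pd.DataFrame:
    return pd.DataFrame([{"sample_id": d.sample_id, "n": d.n,
                          "mean": d.mean, "cv": d.cv} for d in dists])
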