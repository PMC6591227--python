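# Methods

## Scope and data model

All analyses operate on three kinds of input, each of which the
`synthetic_data` module can generate with known ground truth: per-cell
flow-cytometry event tables (forward scatter, side scatter, one green
fluorescence channel, linear arbitrary units ≥ 0), cell-count growth
curves (daily samples, counts per well/field), and parameter files. Time
is in days throughout; drug dose in µg/mL Puromycin; inducer dose in
ng/mL Doxycycline.

## Cytometry processing

**Gating.** Debris is excluded by an adaptive density gate in
(log₁₀ FSC, log₁₀ SSC): a 64×64 2-D histogram smoothed with a Gaussian
kernel (σ = 1.5 bins) assigns each event the density of its bin, and
events below the `density_quantile` quantile of that density are dropped.
The estimator and bandwidth are free choices; any density estimate
satisfying the same contract (quantile-thresholded retention) would do.
After gating at most 20 000 events are kept, mirroring instrument
practice.

**Fluorescence cutoff.** Events at or below 2000 a.u. are removed before
normalization, with a *strict* inequality (an event at exactly 2000 is
excluded). The cutoff separates non-expressing/silenced cells from cells
with an active circuit; `estimate_controls` warns if it is not at least
three autofluorescence SDs above the autofluorescence mean.

**Normalization and noise.** Each surviving event is normalized as
`(FL1 − EGFP_auto) / EGFP_max`, where `EGFP_auto` is the mean of the gated
parental (circuit-free) sample and `EGFP_max` the arithmetic mean of the
brightest calibration-bead cluster, found by 1-D mode detection on a
smoothed log-intensity histogram. Negative normalized values are retained
— the formula does not clip. The summary statistics use the population
conventions: mean = arithmetic mean, σ² = ⟨x²⟩ − ⟨x⟩², CV = σ/μ. CV is
reported as NaN (flagged) when the mean is non-positive.

**Decoupled noise points.** For two noise–mean curves, a dose pair is a
DNP when the replicate-averaged means differ by less than 10 % (relative
to the larger mean) *and* the replicate CVs differ at p < 0.05 under the
two-sided Mann–Whitney U test. The U test is computed by exact
enumeration of all group assignments when both groups have ≤ 8 replicates
(this handles ties exactly; two fully separated groups of 6 give
p = 2/C(12,6) ≈ 0.0022, and 3 vs 6 give 2/C(9,3) ≈ 0.0238), and by the
tie-corrected normal approximation otherwise. Replicate counts too small
to ever reach the requested α (e.g. 3 vs 3, minimum p = 0.1) raise an
explicit infeasibility error rather than silently returning
non-significance.

## Ornstein–Uhlenbeck expression dynamics

Single-cell *log* expression follows a stationary OU process, so the
population law is lognormal, consistent with the log-Gaussian fits used
by the population model. The update is the exact Gaussian transition
(no Euler–Maruyama discretization error):

    x' = μ + (x − μ) e^(−dt/τ) + sd · √(1 − e^(−2dt/τ)) · z,  z ~ N(0,1)

with default dt = 0.01 d. μ and sd set the stationary law; τ is the
fluctuation relaxation (memory) time — ~2 d for the positive-feedback
circuit, ~0.5 d for the negative-feedback circuit. In the survival
simulation, cells whose expression e^x is below the kill threshold die
with a constant hazard (default calibrated so nearly all sub-threshold
cells die within 1–2 days), cells above it divide with a constant hazard,
and daughters inherit the mother's expression exactly (no partitioning
noise — the model's point is expression memory, not division asymmetry).
This pure-OU model produces populations that either grow within days or
collapse; it cannot produce a multi-week flat phase followed by fast
regrowth, which is the motivation for the multi-state population model.

Memory is estimated the way the sorting experiment measures it: take the
top tail of a stationary ensemble, follow the subpopulation's mean
expression as it relaxes to the ensemble mean, and fit
m(t) = m∞ + Δ·e^(−t/τ). Because the OU conditional mean decays as
e^(−t/τ), the fitted τ is the process memory. A constant series is
unidentifiable and raises an error instead of returning a number.

## Population partition and dynamics

**Partition at t = 0.** Log expression is summarized by a maximum-
likelihood Gaussian fit (μ, σ) of log values. The killed fraction is

    A_D = Φ((ln θ(d) − μ)/σ),   θ(d) = β · d/(K + d)

(θ → 0 at zero dose gives A_D = 0). The persister fraction follows a
Gaussian bell in ln-dose with the standard density prefactor,
A_P(d) = exp(−(ln d − μ′)²/(2σ′²)) / (√(2π)·σ′), evaluated exactly in
that form; a `jacobian=True` switch divides by the dose, giving the true
lognormal pdf, as a sensitivity variant. Since the printed form is a
density amplitude, not automatically a probability, composition clips it
into the surviving mass: a_p = min(A_P, 1 − A_D), a_n = 1 − A_D − a_p
(with a warning when clipping bites). The partition therefore satisfies
A_D + A_P + A_N = 1 to 1e−12 by construction, and at very high dose every
surviving cell is a persister.

**Dynamics.** After removing the dead fraction once at t = 0
(P₀ = a_p·n₀, N₀ = a_n·n₀, G₀ = 0; no ongoing threshold killing), the
persister (P), nongenetically resistant (N) and stably resistant (G)
subpopulations evolve with switching P↔N, conversions P→G and N→G, and
birth/death of N and G:

    dP/dt = r_PN·N − r_NP·P − r_GP·P
    dN/dt = r_NP·P − r_PN·N − r_GN·N + (k_N − g_N)·N
    dG/dt = r_GP·P + r_GN·N + (k_G − g_G)·G

Switching terms cancel in the total, so d(P+N+G)/dt = k_N·N + k_G·G −
g_N·N − g_G·G identically. The deterministic path integrates this with
LSODA at rtol 1e−10; the tests verify it against the matrix-exponential
closed form of the linear system. The stochastic path is an exact
Gillespie realization with the same rate terms as propensities. For
large populations the simulator switches to tau-leaping with steps sized
for ~2 % relative population change (Poisson channel draws, step halving
on overshoot); `leap_threshold=inf` forces the exact algorithm.

**Carrying capacity.** Saturation (confluency) is modeled by damping the
*net growth excess*: the per-cell birth rate becomes
min(k, g + (k−g)(1 − N_tot/capacity)). Every net-growing subpopulation
then saturates at the same confluency level, while net-shrinking
subpopulations are unaffected; at capacity, birth balances death, giving
a critically fluctuating plateau rather than a frozen count.

## Adaptation times

Local growth rates are slopes of ln(count + 1) (the pseudocount tolerates
zeros) over a moving window of 3 timepoints. The three-way rule:

1. If no window rate up to saturation falls to 0 or below, the population
   was never suppressed: adaptation time = 0. "Up to saturation" is
   operationalized as windows before the curve first reaches half of its
   maximum — consistent with the adaptation time being a half-saturation
   time — so the near-zero slopes of an established plateau are not
   mistaken for suppression.
2. If the population dies off (final count at/below a floor of 1 with no
   positive window rate after the minimum), or never regrows to at least
   twice its minimum: adaptation time = ∞.
3. Otherwise the Baranyi–Roberts model is fitted to log counts:

       A(t) = t + (1/μ)·ln(e^(−μt) + e^(−h₀) − e^(−μt−h₀))
       y(t) = y₀ + μ·A(t) − ln(1 + (e^(μ·A(t)) − 1)/e^(y_max − y₀))

   by least squares with Powell's method (xtol 1e−8, ≤ 10⁴ evaluations,
   8 restarts; μ and h₀ are fitted on the log scale to stay positive).
   Initialization takes y₀/y_max from the observed extremes, μ from the
   largest window slope, and the lag h₀/μ from the last slow window
   *before* the fastest window (plateau windows are also slow but are not
   lag). The adaptation time is where the fitted curve crosses
   (y₀ + y_max)/2 — the log-scale midpoint, i.e. the geometric mean of
   the baseline and plateau counts. Fitting on log rather than linear
   counts is a deliberate choice (it makes the fit invariant to count
   rescaling up to the level parameters); the fitted crossing is reported
   as ∞ if the curve never reaches the midpoint.

Group comparisons report the mean and SEM of *finite* adaptation times;
infinite (never-recovering) replicates are excluded from the mean but
participate in the Mann–Whitney ranking as largest values.

## The synthetic generator and default study conditions

The generator emulates: lognormal single-cell EGFP intensities (broad for
mPF, sd_log = 0.9; narrow for mNF, sd_log = 0.3; matched back-transformed
means ≈ 5·10⁴ a.u.), an autofluorescence population (mean 150, SD 40
a.u.), a 3 % silenced/basal subpopulation below the 2000 a.u. cutoff, a
correlated bivariate-lognormal scatter cloud with 5 % diffuse low-scatter
debris, an 8-peak geometric bead ladder from 150 to 2.5·10⁵ a.u.
(within-peak CV 4 %), sigmoidal (Hill coefficient 4) vs
linear-then-saturating inducer dose–responses, and three-phase growth
curves with multiplicative lognormal count noise. The distribution
parameters of the two circuits are free parameters of the study (the
source experiments report the dose–response shapes and the decoupling
criteria rather than fitted values); they were fixed once so that the
default pair forms a valid DNP (mean difference < 10 %, CV difference at
exact p = 0.0022 with 6 replicates per side).

The full in-silico experiment uses per-dose parameters chosen once to
reproduce the qualitative stress–noise cross-over with n₀ = 2000 treated
cells, capacity 20 000, 30 days of daily sampling:

* kill threshold β = 0.45 (normalized units), K = 40 µg/mL;
* persister curves: mPF μ′ = ln 30, σ′ = 0.9 (persisters dominate mPF
  survivors from ~22.5 µg/mL up); mNF μ′ = ln 0.5, σ′ = 0.5 (persister
  formation peaks below the treatment range, so mNF forms essentially no
  persisters at lethal doses);
* shared rates (per day): k_N = k_G = 0.8, g_G = 0.05, switching
  r_PN = 0.002, r_NP = 0.001, conversions r_GP = 0.002, r_GN = 5·10⁻⁴;
* N-cell death increasing with dose: g_N = 0.02 / 0.3 / 0.45 / 0.9 / 2.5
  at 0 / 10 / 22.5 / 35 / 50 µg/mL (interpolated off-panel), encoding
  that nongenetic resistance becomes increasingly insufficient at higher
  stress while stable resistance is not;
* imaging-style counting noise of CV 7 % applied to the simulated counts
  before adaptation analysis, emulating per-field spot-detection counts.

Under these defaults: both circuits grow immediately at 0 and
10 µg/mL; at 22.5 µg/mL mNF grows without adaptation while mPF is
suppressed and adapts after ~8–11 days via P→G conversion; at 50 µg/mL
mNF goes extinct (rare escapes via its few remaining N cells occur in
roughly 1 replicate in 6–10) while mPF reliably adapts.

## Numerical choices and degenerate inputs

* Natural log everywhere; Gaussian tail probabilities via the normal CDF.
* Mann–Whitney: exact enumeration for n ≤ 8 per group, asymptotic with
  tie correction otherwise; SEM over replicates is sample SD/√n, reported
  as NaN for a single replicate rather than 0.
* `fit_log_gaussian` requires positive values (an optional offset shifts
  borderline-negative normalized values) and rejects constant samples
  (σ = 0) as degenerate.
* OU: `dt` must be well below τ; the exact transition makes results
  insensitive to dt beyond sampling resolution.
* SSA initial counts are rounded to integers; trajectories are recorded
  on a uniform grid; populations exceeding a hard cap stop with a
  truncation flag.
* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; identical config + seed reproduces every
  output exactly.

## What the synthetic data does and does not show

The generator reproduces the statistical *structure* the analysis relies
on — lognormal expression with controllable noise, debris needing a gate,
a silenced peak needing a cutoff, bead clusters needing peak detection,
three-phase growth needing lag-model fitting — so a passing suite shows
the machinery is correct and self-consistent. It does not certify
instrument-specific artifacts (spectral spillover, detector saturation,
time drift), real culture effects (media exhaustion, passaging), or the
actual parameter values of any particular cell line; rates and thresholds
here are documented assumptions, not inferred quantities.

## Known limitations

* The population model removes dead cells instantly at t = 0; real
  death-phase kinetics (days of decline) are not represented, which makes
  early suppression detectable mainly through counting noise.
* At the intermediate 35 µg/mL dose the default parameterization gives
  the high-noise circuit a slightly *shorter* adaptation delay than the
  low-noise circuit; the relative ordering at intermediate stress is
  sensitive to the switching/conversion rates, and only the low/high-dose
  cross-over is treated as a robust model prediction.
* The rate scan classifies deterministic (ODE) trajectories; delayed
  adaptation that only manifests through stochastic suppression of small
  subpopulations appears there as slow immediate growth.
* Single fluorescence channel; no compensation/spillover. FCS binary I/O
  is not implemented — CSV event tables are the canonical format.
* Drug removal/re-treatment protocols are not modeled beyond re-running
  with a different rate set.
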