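# noisevolve

Tools for studying how **gene-expression noise**, controlled by regulatory
network architecture, shapes the evolution of drug resistance in mammalian
cell populations.

The scientific setting: two synthetic gene circuits drive the same
Puromycin-resistance gene (*PuroR*) in isogenic CHO cells — a
positive-feedback circuit (**mPF**, high noise, long expression memory
~2 days) and a negative-feedback circuit (**mNF**, low noise, short memory
~0.5 days). At *decoupled noise points* (DNPs) the two circuits have the
same mean expression but very different cell-to-cell variability
(CV = σ/μ), so any difference in survival and adaptation under Puromycin
is attributable to noise and network structure, not to mean expression.

`noisevolve` implements the computational machinery of that experiment as
a tested, fully synthetic-data-driven pipeline:

| module | what it does |
| --- | --- |
| `synthetic_data` | generates cytometry event tables (lognormal EGFP + autofluorescence + debris + silenced peak), 8-peak calibration beads, inducer dose–response panels, and three-phase growth curves with known ground truth |
| `cytometry` | density gating on (log FSC, log SSC), the 2000 a.u. fluorescence cutoff (strict `>`), normalization `(FL1 − EGFP_auto)/EGFP_max`, mean/CV statistics, noise–mean curves, DNP detection with the exact two-sided Mann–Whitney U test |
| `ou_model` | exact-transition Ornstein–Uhlenbeck log-expression dynamics (`x' = μ + (x−μ)e^{−dt/τ} + sd·√(1−e^{−2dt/τ})·z`) with threshold-gated division/death, plus expression-memory (τ) estimation from sorted-subpopulation relaxation |
| `popdyn` | the dead/persister/nongenetic/genetic (D/P/N/G) partition: `A_D = Φ((ln θ(d) − μ)/σ)` with a Michaelis–Menten kill threshold `θ(d) = β·d/(K+d)`, a Gaussian-in-ln-dose persister fraction, and P/N/G dynamics by linear ODE or exact Gillespie simulation |
| `adaptation` | moving-window growth rates, the 0 / finite / ∞ adaptation-time rule, and Baranyi–Roberts growth-model fitting (Powell, multi-start) to extract half-saturation adaptation times |
| `pipeline` + `cli` | the end-to-end in-silico evolution experiment across the 0/10/22.5/35/50 µg/mL Puromycin panel |

## Worked example

```python
from noisevolve import pipeline

result = pipeline.run_experiment(pipeline.ExperimentConfig(replicates=6, seed=7))
print(pipeline.summarize(result)["adaptation"].to_string(index=False))
```

```
circuit  dose   n  n_finite  n_extinct  mean_adaptation_time  sem_adaptation_time  adapted_fraction
    mNF   0.0 6.0       6.0        0.0              0.000000             0.000000          1.000000
    mNF  10.0 6.0       6.0        0.0              0.000000             0.000000          1.000000
    mNF  22.5 6.0       6.0        0.0              0.000000             0.000000          1.000000
    mNF  35.0 6.0       6.0        0.0             15.473032             2.834484          1.000000
    mNF  50.0 6.0       1.0        4.0             12.129308                  NaN          0.166667
    mPF   0.0 6.0       6.0        0.0              0.000000             0.000000          1.000000
    mPF  10.0 6.0       6.0        0.0              0.000000             0.000000          1.000000
    mPF  22.5 6.0       6.0        0.0              8.482246             1.702346          1.000000
    mPF  35.0 6.0       6.0        0.0              8.454346             1.731315          1.000000
    mPF  50.0 6.0       6.0        0.0              9.606952             2.024943          1.000000
```

Reading the table: at 0 and 10 µg/mL both circuits grow without adaptation
(time 0). At 22.5 µg/mL the low-noise mNF population still grows
immediately while the high-noise mPF population is suppressed for days and
adapts late (mean ≈ 8.5 d) through persister-to-stable-resistant
conversion. At 50 µg/mL the pattern inverts: most mNF replicates go
extinct (4/6 here, with the rest stalling as a handful of idle persisters)
while every mPF replicate eventually adapts — noise hurts at low stress
and rescues at high stress.

The same workflow is available from the shell:

```bash
noisevolve run --out results/           # full experiment + figures
noisevolve simulate beads --out beads.csv --seed 1
noisevolve adapt --curves growth.csv --out adaptation.csv
```

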