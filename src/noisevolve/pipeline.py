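"""End-to-end in-silico drug-treatment experiment.

Composes the modules into the full workflow: generate decoupled-noise-point
(DNP) populations for the high-noise (mPF) and low-noise (mNF) circuits,
estimate normalization controls from synthetic parental and bead samples,
gate/filter/normalize, fit the log-Gaussian expression model per circuit,
compute the initial dead/persister/nongenetic partition per Puromycin dose,
run the stochastic population dynamics per replicate, and extract and
compare adaptation times across the dose panel (default 0, 10, 22.5, 35,
50 ug/mL).

The default parameterization reproduces the qualitative cross-over: the
high-noise circuit suffers at low dose (delayed adaptation while the
low-noise circuit grows without adapting) but is the only one that adapts
at the highest dose, where the low-noise population perishes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptation, cytometry, popdyn, synthetic_data

DEFAULT_DOSES = (0.0, 10.0, 22.5, 35.0, 50.0)

# per-dose death rate of nongenetically resistant cells: increasingly
# greater than the (dose-independent) death rate of stably resistant cells
DEFAULT_GN_BY_DOSE = {0.0: 0.02, 10.0: 0.3, 22.5: 0.45, 35.0: 0.9, 50.0: 2.5}


@dataclass
class ExperimentConfig:
    doses: tuple = DEFAULT_DOSES
    replicates: int = 6
    n0: float = 2000.0
    capacity: float = 20_000.0
    t_max: float = 30.0
    n_events: int = 20_000
    # multiplicative CV of the imaging-based cell counting; the experimental
    # growth curves come from per-field spot detection, not exact censuses
    count_noise_cv: float = 0.05
    seed: int = 0
    # kill-threshold law (normalized expression units, ug/mL)
    beta: float = 0.45
    K: float = 40.0
    # persister-induction curves per circuit (ln ug/mL)
    persister: dict = field(default_factory=lambda: {
        "mPF": {"mu_prime": float(np.log(30.0)), "sigma_prime": 0.9},
        "mNF": {"mu_prime": float(np.log(0.5)), "sigma_prime": 0.5},
    })
    # shared switching/conversion/growth rates; g_n varies with dose
    r_pn: float = 0.002
    r_np: float = 0.001
    r_gp: float = 0.002
    r_gn: float = 5e-4
    k_n: float = 0.8
    k_g: float = 0.8
    g_g: float = 0.05
    g_n_by_dose: dict = field(default_factory=lambda: dict(DEFAULT_GN_BY_DOSE))

    def rates_at(self, dose: float) -> popdyn.RateSet:
        g_n = self.g_n_by_dose.get(dose)
        if g_n is None:  # interpolate for off-panel doses
            known = sorted(self.g_n_by_dose)
            g_n = float(np.interp(dose, known,
                                  [self.g_n_by_dose[d] for d in known]))
        return popdyn.RateSet(r_pn=self.r_pn, r_np=self.r_np, r_gp=self.r_gp,
                              r_gn=self.r_gn, k_n=self.k_n, k_g=self.k_g,
                              g_n=g_n, g_g=self.g_g)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "doses" in raw:
            raw["doses"] = tuple(float(d) for d in raw["doses"])
        if "g_n_by_dose" in raw:
            raw["g_n_by_dose"] = {float(k): float(v)
                                  for k, v in raw["g_n_by_dose"].items()}
        return cls(**raw)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    fits: dict                       # circuit -> LogNormalFit
    fractions: pd.DataFrame          # circuit x dose -> A_D, A_P, A_N
    adaptation_table: pd.DataFrame   # per replicate
    trajectories: dict               # (circuit, dose, rep) -> PopulationTrajectory
    dnp_report: pd.DataFrame
    manifest: dict


def _fit_circuits(config: ExperimentConfig, rng_seq: np.random.SeedSequence
                  ) -> tuple[dict, pd.DataFrame]:
    """Cytometry leg: simulate, gate, filter, normalize, fit per circuit."""
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng_seq.spawn(4)]
    parental = synthetic_data.simulate_parental(8000, seed=seeds[0])
    beads = synthetic_data.simulate_beads(seed=seeds[1])
    controls = cytometry.estimate_controls(parental, beads)

    fits: dict[str, popdyn.LogNormalFit] = {}
    dists: dict[str, list] = {}
    for i, spec in enumerate((synthetic_data.MPF, synthetic_data.MNF)):
        reps = []
        for r in range(6):  # replicate cytometry samples at the DNP
            table = synthetic_data.simulate_events(
                spec, config.n_events, seed=seeds[2 + i] + 7919 * r)
            gated = cytometry.gate_events(table, density_quantile=0.05)
            kept = cytometry.filter_fluorescence(gated, controls.egfp_cutoff)
            reps.append(cytometry.normalize(kept, controls))
        dists[spec.name] = reps
        pooled = np.concatenate([d.values for d in reps])
        fits[spec.name] = popdyn.fit_log_gaussian(pooled)

    # DNP verification report: mean match + CV rank test across replicates
    rows = []
    from ._stats import mann_whitney
    means = {c: np.array([d.mean for d in ds]) for c, ds in dists.items()}
    cvs = {c: np.array([d.cv for d in ds]) for c, ds in dists.items()}
    mean_a, mean_b = means["mPF"].mean(), means["mNF"].mean()
    rel = abs(mean_a - mean_b) / max(mean_a, mean_b)
    rows.append({
        "mean_mPF": mean_a, "mean_mNF": mean_b, "mean_rel_diff": rel,
        "cv_mPF": cvs["mPF"].mean(), "cv_mNF": cvs["mNF"].mean(),
        "p_mean": mann_whitney(means["mPF"], means["mNF"]).p_value,
        "p_cv": mann_whitney(cvs["mPF"], cvs["mNF"]).p_value,
        "is_dnp": rel < 0.10 and mann_whitney(cvs["mPF"], cvs["mNF"]).p_value < 0.05,
    })
    return fits, pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the full circuit x dose x replicate in-silico evolution assay."""
    config = config or ExperimentConfig()
    root = np.random.SeedSequence(config.seed)
    cyto_seq, dyn_seq = root.spawn(2)
    fits, dnp_report = _fit_circuits(config, cyto_seq)

    frac_rows = []
    adapt_rows = []
    trajectories = {}
    rep_seeds = dyn_seq.generate_state(10_000)
    k = 0
    for circuit, fit in fits.items():
        pers = popdyn.PersisterParams(**config.persister[circuit])
        thresh = popdyn.KillThresholdParams(beta=config.beta, K=config.K)
        for dose in config.doses:
            fracs = popdyn.initial_fractions(fit, thresh, pers, dose)
            frac_rows.append({"circuit": circuit, "dose": dose,
                              "A_D": fracs.a_d, "A_P": fracs.a_p,
                              "A_N": fracs.a_n,
                              "persister_share_of_survivors":
                                  (fracs.a_p / fracs.surviving
                                   if fracs.surviving > 0 else float("nan"))})
            rates = config.rates_at(dose)
            for rep in range(config.replicates):
                seed = int(rep_seeds[k] % 2**31)
                k += 1
                traj = popdyn.simulate_stochastic(
                    fracs, rates, config.n0, config.t_max, seed=seed,
                    capacity=config.capacity)
                trajectories[(circuit, dose, rep)] = traj
                counts = traj.n_tot
                if config.count_noise_cv > 0:
                    obs_rng = np.random.default_rng(seed + 1)
                    s = np.sqrt(np.log1p(config.count_noise_cv**2))
                    counts = counts * obs_rng.lognormal(-s**2 / 2, s,
                                                        size=len(counts))
                curve = adaptation.GrowthCurve(
                    traj.t, counts, replicate_id=f"r{rep + 1}",
                    condition=f"{circuit}@{dose}")
                res = adaptation.estimate_adaptation(curve, seed=seed)
                adapt_rows.append({
                    "circuit": circuit, "dose": dose, "replicate": rep + 1,
                    "adaptation_time": res.adaptation_time,
                    "suppressed": res.suppressed,
                    # adapted: immediate or eventually recovered growth;
                    # a handful of idling persisters is not adaptation
                    "adapted": bool(np.isfinite(res.adaptation_time)),
                    "survived": traj.n_tot[-1] > 1.0,
                    "final_count": float(traj.n_tot[-1]),
                    "seed": seed})

    cfg_dict = asdict(config)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_runs": k,
    }
    return ExperimentResult(config=config, fits=fits,
                            fractions=pd.DataFrame(frac_rows),
                            adaptation_table=pd.DataFrame(adapt_rows),
                            trajectories=trajectories,
                            dnp_report=dnp_report, manifest=manifest)


def summarize(result: ExperimentResult) -> dict[str, pd.DataFrame]:
    """Condition-level tables: adaptation times, composition, DNP check."""
    at = result.adaptation_table
    if at.empty:
        raise ValueError("empty result bundle")

    def agg(group: pd.DataFrame) -> pd.Series:
        times = group["adaptation_time"].to_numpy()
        finite = times[np.isfinite(times)]
        return pd.Series({
            "n": len(times),
            "n_finite": len(finite),
            "n_extinct": int((~group["survived"]).sum()),
            "mean_adaptation_time": finite.mean() if len(finite) else np.nan,
            "sem_adaptation_time": (finite.std(ddof=1) / np.sqrt(len(finite))
                                    if len(finite) > 1 else np.nan),
            "adapted_fraction": group["adapted"].mean(),
        })
    adaptation_summary = (at.groupby(["circuit", "dose"])
                          .apply(agg, include_groups=False).reset_index())
    return {"adaptation": adaptation_summary,
            "composition": result.fractions,
            "dnp": result.dnp_report}


def write_outputs(result: ExperimentResult, outdir,
                  figures: bool = False) -> None:
    """Persist tables, trajectories, manifest (optionally PNG figures)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = summarize(result)
    result.adaptation_table.to_csv(outdir / "adaptation_replicates.csv",
                                   index=False)
    tables["adaptation"].to_csv(outdir / "adaptation_summary.csv", index=False)
    tables["composition"].to_csv(outdir / "composition.csv", index=False)
    tables["dnp"].to_csv(outdir / "dnp_report.csv", index=False)
    traj_frames = []
    for (circuit, dose, rep), traj in result.trajectories.items():
        df = traj.to_frame()
        df.insert(0, "circuit", circuit)
        df.insert(1, "dose", dose)
        df.insert(2, "replicate", rep + 1)
        traj_frames.append(df)
    pd.concat(traj_frames).to_csv(outdir / "trajectories.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    if figures:
        _write_figures(result, outdir)


def _write_figures(result: ExperimentResult, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    doses = sorted({d for (_, d, _) in result.trajectories})
    fig, axes = plt.subplots(1, len(doses), figsize=(3.2 * len(doses), 3),
                             sharey=True)
    axes = np.atleast_1d(axes)
    colors = {"mPF": "tab:red", "mNF": "tab:blue"}
    for ax, dose in zip(axes, doses):
        for (circuit, d, rep), traj in result.trajectories.items():
            if d != dose:
                continue
            ax.semilogy(traj.t, traj.n_tot + 1, color=colors[circuit],
                        alpha=0.5, lw=1,
                        label=circuit if rep == 0 else None)
        ax.set_title(f"{dose} µg/mL")
        ax.set_xlabel("time (days)")
    axes[0].set_ylabel("cells + 1")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(outdir / "growth_curves.png", dpi=150)
    plt.close(fig)
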