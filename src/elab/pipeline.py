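"""End-to-end orchestration: generate -> filter -> behavioral fits -> DDM ->
mixture -> physiology -> cluster inference -> value integration.

Every stage consumes an independent substream of the master seed, writes its
outputs under the run directory, and records itself in a manifest
(config snapshot, per-stage seeds, output hashes, timings) so that a rerun
from the same manifest reproduces the deterministic outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, ddm, mixture, physio, spm, taskgen

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """All analysis thresholds surfaced as named keys (defaults are the
    study's): anticipation cutoff 0.150 s, IBI artifact rule 30%, burst
    threshold 3 SD, burst merge 20 ms / minimum 25 ms, Tukey 1.5 IQR,
    cluster p-threshold 0.05 with >100 ms (iHR) / >20 ms (EMG) runs,
    10000 permutations, mixture components 1..5."""

    n_participants: int = 12
    seed: int = 0
    with_signals: bool = True
    anticipation_min_rt: float = 0.150
    ibi_max_change: float = 0.30
    burst_n_sd: float = 3.0
    burst_merge_s: float = 0.020
    burst_min_s: float = 0.025
    iqr_k: float = 1.5
    cluster_p_thres: float = 0.05
    cluster_min_ihr_s: float = 0.100
    cluster_min_emg_s: float = 0.020
    n_permutations: int = 10000
    mixture_k_max: int = 5
    mixture_restarts: int = 20
    mcmc_chains: int = 3
    mcmc_iter: int = 1500
    mcmc_warmup: int = 500
    ddm_mode: str = "ml"
    run_behavior_mcmc: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _hash_file(path: Path) -> str:
    h = hashlib.sha1()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    Stage errors halt the run with the stage's diagnostic; outputs of
    completed stages are preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["simulate", "behavior", "ddm", "mixture", "physio", "spm", "value"],
            master.spawn(7),
        )
    }
    manifest: dict = {
        "config": asdict(config),
        "stage_seeds": stage_seeds,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _hash_file(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    # --- simulate
    t0 = time.time()
    cfg = taskgen.StudyConfig(
        n_participants=config.n_participants, rng_seed=stage_seeds["simulate"]
    )
    cohort = taskgen.generate_cohort(
        cfg, rng=np.random.default_rng(stage_seeds["simulate"]), with_signals=config.with_signals
    )
    trials_path = out / "trials.csv"
    taskgen.write_trials_csv(cohort["trials"], trials_path)
    sv_path = out / "subjective_values.csv"
    cohort["sv"].to_csv(sv_path, index=False)
    record("simulate", t0, [trials_path, sv_path])

    # --- behavioral filtering and summaries
    t0 = time.time()
    threat = cohort["trials"][cohort["trials"]["trial_type"] == "threat"]
    kept, n_anticip, pct, n_missing = behavior.filter_anticipations(
        threat, min_rt=config.anticipation_min_rt
    )
    summary = behavior.avoidance_summary(kept)
    summary_path = out / "avoidance_summary.csv"
    summary.to_csv(summary_path, index=False)
    wide = summary.pivot(index="participant_id", columns="condition", values="p_avoid")
    wtest = behavior.wilcoxon_vs_chance(
        wide["unpredictable"].dropna().to_numpy(), seed=stage_seeds["behavior"]
    )
    behavior_out = {
        "n_anticipations": n_anticip,
        "pct_anticipations": pct,
        "n_missing": n_missing,
        "wilcoxon_unpredictable_vs_chance": {k: v for k, v in wtest.items() if k != "ci_d"},
    }
    fit = None
    if config.run_behavior_mcmc:
        mcfg = behavior.MCMCConfig(
            n_chains=config.mcmc_chains,
            n_iter=config.mcmc_iter,
            n_warmup=config.mcmc_warmup,
            seed=stage_seeds["behavior"],
        )
        fit = behavior.fit_hierarchical_logistic(
            behavior.ModelSpec(), behavior.PriorSpec(), kept, mcfg
        )
        eff = behavior.summarize_effect(fit, "b_condition")
        behavior_out["condition_effect"] = {
            "median": eff.median,
            "cri_95": eff.cri_95,
            "p_below_zero": eff.p_below_zero,
            "bf10": eff.bayes_factor_10,
        }
    behav_path = out / "behavior.json"
    behav_path.write_text(json.dumps(behavior_out, indent=1, default=float))
    record("behavior", t0, [summary_path, behav_path])

    # --- DDM comparison grid
    t0 = time.time()
    table = ddm.compare_designs(
        kept, mode=config.ddm_mode, seed=stage_seeds["ddm"], n_starts=5
    )
    ddm_path = out / "ddm_comparison.csv"
    table.drop(columns=["best"]).assign(best=table["best"]).to_csv(ddm_path, index=False)
    record("ddm", t0, [ddm_path])

    # --- mixture
    t0 = time.time()
    best_k, bic_table, fits = mixture.select_K(
        kept,
        K_range=range(1, config.mixture_k_max + 1),
        rng=stage_seeds["mixture"],
        n_restarts=config.mixture_restarts,
    )
    labels = mixture.assign_classes(fits[best_k])
    mix_path = out / "mixture.json"
    mix_path.write_text(
        json.dumps(
            {
                "best_K": best_k,
                "bic_table": bic_table.to_dict("records"),
                "coefficients": fits[best_k].coefficients.tolist(),
                "mixing_proportions": fits[best_k].mixing_proportions.tolist(),
                "labels": labels.to_dict("records"),
            },
            indent=1,
            default=float,
        )
    )
    record("mixture", t0, [mix_path])

    cluster_out: dict = {}
    if config.with_signals:
        # --- physiology: ECG chain to z-scored iHR epochs
        t0 = time.time()
        epochs_z, epochs_bpm, trials_by_p = {}, {}, {}
        for prof in cohort["profiles"]:
            pid = prof.participant_id
            trace = cohort["signals"][pid]["ecg"]
            filtered = physio.bandpass_zero_phase(trace.samples, trace.fs, 1.0, 100.0)
            beats = physio.detect_r_peaks(filtered, trace.fs)
            ibis = physio.correct_ibis(
                physio.compute_ibis(beats), max_change=config.ibi_max_change
            )
            ep = physio.epoch_ihr(ibis, trace.event_markers)
            ptrials = cohort["trials"][
                cohort["trials"]["participant_id"] == pid
            ].set_index("trial").loc[ep.trial_index].reset_index()
            responded = ptrials["response"].isin(["avoid", "approach"]) | (
                ptrials["trial_type"] == "neutral"
            )
            sel = responded.to_numpy() & np.isfinite(ptrials["rt_s"].to_numpy(float))
            ep.values = ep.values[sel]
            ep.trial_index = ep.trial_index[sel]
            epochs_bpm[pid] = ep
            epochs_z[pid] = physio.zscore_within_participant(ep)
            trials_by_p[pid] = ptrials[sel].reset_index(drop=True)
        record("physio", t0, [])

        # --- cluster inference on the condition effect (threat formula)
        t0 = time.time()
        betas = spm.fit_trialwise_glm(epochs_z, trials_by_p, formula=1)
        rng_spm = np.random.default_rng(stage_seeds["spm"])
        for reg in ("intercept", "condition"):
            cl = spm.find_clusters(
                betas, reg, p_thres=config.cluster_p_thres,
                min_duration=config.cluster_min_ihr_s,
            )
            cl = spm.permutation_test(betas, cl, n_perm=config.n_permutations, rng=rng_spm)
            cluster_out[reg] = [
                {
                    "sign": c.sign,
                    "window_s": [c.start_time, c.end_time],
                    "t_mass": c.t_mass,
                    "p_corr": c.p_corr,
                }
                for c in cl
            ]
        spm_path = out / "clusters.json"
        spm_path.write_text(json.dumps(cluster_out, indent=1, default=float))
        record("spm", t0, [spm_path])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def make_report(run_dir: str | Path) -> Path:
    """Human-readable summary of a completed run (partial runs get gaps
    flagged); also draws the defective RT densities per response type."""
    run = Path(run_dir)
    lines = ["# Elevator-task analysis report", ""]
    trials_path = run / "trials.csv"
    if trials_path.exists():
        trials = pd.read_csv(trials_path)
        threat = trials[trials["trial_type"] == "threat"]
        responded = threat[threat["response"].isin(["avoid", "approach"])]
        lines.append(f"Trials: {len(trials)} total, {len(threat)} threat, "
                     f"{len(responded)} responded threat trials")
        for cond, g in responded.groupby("condition"):
            lines.append(f"  P(avoid | {cond}) = {(g['response'] == 'avoid').mean():.3f}")
        _defective_density_figure(responded, run / "defective_rt_density.png")
        lines.append("Defective RT densities: defective_rt_density.png")
    else:
        lines.append("Trials: MISSING")
    for name, title in [
        ("avoidance_summary.csv", "Avoidance summary"),
        ("behavior.json", "Behavioral inference"),
        ("ddm_comparison.csv", "DDM design comparison"),
        ("mixture.json", "Mixture model"),
        ("clusters.json", "Cluster inference"),
    ]:
        path = run / name
        if not path.exists():
            lines.append(f"{title}: MISSING")
            continue
        if name.endswith(".json"):
            lines.append(f"## {title}")
            lines.append(path.read_text())
        else:
            lines.append(f"## {title}")
            lines.append(pd.read_csv(path).to_string(index=False))
    report = run / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _defective_density_figure(responded: pd.DataFrame, path: Path) -> None:
    """Response-type RT densities weighted by each type's relative frequency,
    so the avoid and approach curves jointly integrate to one."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(6, 3))
    rt = responded["rt_s"].to_numpy(float)
    grid = np.linspace(0.0, max(1.5, np.nanmax(rt)), 200)
    for resp, style in [("avoid", "-"), ("approach", ":")]:
        sub = responded[responded["response"] == resp]["rt_s"].to_numpy(float)
        weight = len(sub) / len(responded)
        if len(sub) > 1 and np.ptp(sub) > 0:
            ax.plot(grid, weight * gaussian_kde(sub)(grid), style, label=resp)
        else:
            ax.plot([], [], style, label=f"{resp} (n={len(sub)})")
    ax.set_xlabel("RT (s)")
    ax.set_ylabel("defective density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
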