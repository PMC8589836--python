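"""End-to-end orchestration: generate -> analyze -> report.

A :class:`RunConfig` names the stages to run, per-stage parameter blocks, a
global seed and an output directory.  The global seed is spawned
deterministically into per-stage seeds, every stage writes its artifacts
under the output directory, and a single summary JSON collects the
headline metrics (stoichiometry n_hat/p_hat, k_min fit, tau_avg, pause
metrics, kMC velocity ratio).  Identical config + seed produces
byte-identical summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import coordination, engagements, io, kmc, stoich, synth, trap

__all__ = ["RunConfig", "ConfigError", "DependencyError", "run_pipeline", "run_stage"]

logger = logging.getLogger("motorlab")

KNOWN_STAGES = ("synth", "stoich", "coordination", "engage", "trap", "kmc")


class ConfigError(ValueError):
    """Raised for unknown stage names or malformed configuration."""


class DependencyError(FileNotFoundError):
    """Raised when a stage needs an input artifact that does not exist."""


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: list(KNOWN_STAGES))
    params: dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "motorlab_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in KNOWN_STAGES:
                raise ConfigError(f"unknown stage name: {stage!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _stage_seed(config: RunConfig, stage: str) -> np.random.Generator:
    idx = KNOWN_STAGES.index(stage)
    child = np.random.SeedSequence(config.seed).spawn(len(KNOWN_STAGES))[idx]
    return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_synth(params: dict, rng, out: Path) -> dict:
    """Write one example dataset per generator (with ground truth)."""
    comp = synth.MotorComposition(per_subunit_label_prob=params.get("label_prob", 0.66))
    trace, truth = synth.gen_photobleach_trace(comp, seed=rng, trace_id="demo_cy3")
    io.write_intensity_trace(trace, out / "photobleach_trace.tsv")

    cy5, truths = synth.gen_engagement_trajectory(
        synth.EngagementKinetics(), seed=rng, trace_id="demo_cy5"
    )
    io.write_intensity_trace(cy5, out / "engagement_trace.tsv")
    io.write_events([t.event for t in truths], out / "engagement_truth_events.tsv")

    ext, ext_truth = synth.gen_extension_trace(seed=rng, trace_id="demo_trap")
    io.write_extension_trace(ext, out / "extension_trace.tsv")
    io.write_pauses(ext_truth.pauses, out / "extension_truth_pauses.tsv")
    return {
        "photobleach_true_label_count": truth.n_labels,
        "n_true_engagements": len(truths),
        "n_true_pauses": ext_truth.pauses.n_pauses,
    }


def _stage_stoich(params: dict, rng, out: Path) -> dict:
    n_traces = params.get("n_traces", 486)
    p_label = params.get("label_prob", 0.66)
    n_subunits = params.get("n_subunits", 5)
    amplitude = params.get("step_amplitude", 100.0)
    noise_sd = params.get("noise_sd", amplitude / 3.0)

    input_path = params.get("input_counts")
    if input_path is not None:
        path = Path(input_path)
        if not path.exists():
            raise DependencyError(f"missing upstream artifact: {path}")
        counts = np.loadtxt(path, dtype=int)
    else:
        labels = synth.sample_zero_truncated_binomial(n_subunits, p_label, n_traces, rng)
        comp = synth.MotorComposition(n_subunits=n_subunits, per_subunit_label_prob=p_label)
        min_amp = params.get("min_amplitude") or 0.6 * amplitude
        traces = [
            synth.gen_photobleach_trace(
                comp, amplitude, noise_sd=noise_sd, seed=rng, n_labels=int(k)
            )[0]
            for k in labels
        ]
        counts = np.asarray([r.n_steps for r in stoich.count_steps_dataset(traces, min_amp)])
        counts = counts[counts >= 1]
    report = stoich.stoichiometry_report(
        counts,
        candidate_n=tuple(params.get("candidates") or stoich.DEFAULT_CANDIDATE_N),
        truncate_zero=params.get("truncate_zero", True),
    )
    report["table"].to_csv(out / "stoich_candidates.tsv", sep="\t")
    fit = report["fit"]
    return {"n_hat": fit.n_hat, "p_hat": fit.p_hat, "n_counts": int(counts.size)}


def _stage_coordination(params: dict, rng, out: Path) -> dict:
    n = params.get("n_subunits", 5)
    grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    curves = {k: coordination.predicted_activity(k, grid, n) for k in range(1, n + 1)}

    input_path = params.get("input_observations")
    if input_path is not None:
        path = Path(input_path)
        if not path.exists():
            raise DependencyError(f"missing upstream artifact: {path}")
        obs = np.loadtxt(path)
    else:
        k_true = params.get("k_min_true", 3)
        p_obs = np.array(params.get("doping_points", [0.0, 0.2, 0.4, 0.6, 0.8]))
        noise = params.get("obs_noise_sd", 0.05)
        obs = np.column_stack(
            [p_obs, coordination.predicted_activity(k_true, p_obs, n) + rng.normal(0, noise, p_obs.size)]
        )
    fit = coordination.fit_kmin(obs, n)
    io.write_report(
        {
            "doping_grid": grid,
            "activity_curves": {str(k): v for k, v in curves.items()},
            "k_min_hat": fit.k_min,
            "residual_sums": fit.residual_sums,
        },
        out / "coordination_fit.json",
    )
    return {"k_min_hat": fit.k_min}


def _stage_engage(params: dict, rng, out: Path) -> dict:
    n_traj = params.get("n_trajectories", 50)
    duration = params.get("duration_s", 240.0)
    threshold_sd = params.get("threshold_sd") or 2.5
    orders = tuple(params.get("orders") or (1, 2))
    kin = synth.EngagementKinetics()
    sequences, all_gaps = [], []
    for i in range(n_traj):
        trace, _ = synth.gen_engagement_trajectory(kin, duration, seed=rng, trace_id=f"m{i}")
        events = engagements.idealize_engagements(trace, threshold_multiple=threshold_sd)
        sequences.append(events)
        all_gaps.append(engagements.gap_times(events))
    gaps = np.concatenate([g for g in all_gaps if g.size])
    gap_fit = engagements.fit_exponential_mixture(gaps, candidate_orders=orders)
    flat = [ev for seq in sequences for ev in seq]
    freqs = engagements.engagement_frequencies(flat, n_traj * duration)
    probs, _ = engagements.class_transition_matrix(sequences)
    packaged = [engagements.count_packaged_dna(seq) for seq in sequences]
    io.write_events(flat, out / "engagement_events.tsv")
    np.savetxt(out / "transition_matrix.tsv", probs, delimiter="\t")
    return {
        "tau_avg_s": gap_fit.tau_avg,
        "gap_components": gap_fit.n_components,
        "events_per_minute": freqs["per_minute"],
        "mean_packaged_dna": float(np.mean(packaged)),
    }


def _stage_trap(params: dict, rng, out: Path) -> dict:
    n_traces = params.get("n_traces", 5)
    window = params.get("window") or 0.1
    threshold = params.get("threshold") or "variance"
    plateau_band = params.get("plateau_band") or 50.0
    sim = synth.TrapSimParams(**params.get("sim", {}))
    wlc = trap.WLCParams()
    metrics = []
    for i in range(n_traces):
        ext, _ = synth.gen_extension_trace(sim, wlc, seed=rng, trace_id=f"t{i}")
        ext = ext.with_bp(wlc)
        v = trap.rolling_velocity(ext, window)
        pauses = trap.detect_pauses(
            v, ext.times, threshold=threshold, plateau_band_bp_s=plateau_band
        )
        metrics.append(trap.trace_metrics(ext, pauses, window_s=window, velocity_bp_s=v))
    io.write_pauses(pauses, out / "pause_table_last_trace.tsv")
    return {
        "mean_pause_free_velocity_bp_s": float(
            np.mean([m.pause_free_velocity_bp_s for m in metrics])
        ),
        "mean_pause_frequency_per_kb": float(
            np.mean([m.pause_frequency_per_kb for m in metrics])
        ),
        "n_traces": n_traces,
    }


def _stage_kmc(params: dict, rng, out: Path) -> dict:
    min_successes = params.get("min_successes", 200)
    seed = int(rng.integers(2**31))
    summary, ratio = kmc.run_paper_conditions(seed, min_successes)
    summary.to_csv(out / "kmc_conditions.tsv", sep="\t")
    return {"velocity_ratio_0_vs_1_2_inactive": ratio}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "stoich": _stage_stoich,
    "coordination": _stage_coordination,
    "engage": _stage_engage,
    "trap": _stage_trap,
    "kmc": _stage_kmc,
}


def run_stage(config: RunConfig, stage: str) -> dict:
    if stage not in KNOWN_STAGES:
        raise ConfigError(f"unknown stage name: {stage!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _stage_seed(config, stage)
    logger.info("running stage %s", stage)
    return _STAGE_FUNCS[stage](config.params.get(stage, {}), rng, out)


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages and write a summary JSON report bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    summary = {"seed": config.seed, "stages": {}}
    for stage in config.stages:
        summary["stages"][stage] = run_stage(config, stage)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_report(summary, out / "summary.json")
    return summary
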