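"""Configuration and orchestration of the analysis stages.

A :class:`RunConfig` (loadable from YAML) selects stages and parameters; the
pipeline runs simulate -> trace analysis -> histograms -> staged fit -> model
selection -> kinetics -> ensemble fits, writing a machine-readable JSON
bundle.  Every stage derives its randomness from the single config seed, so
the same config gives byte-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from gatefret import synthetic_data as sd
from gatefret.fret_histograms import (
    average_replicates,
    fit_staged_mixture,
    histograms_from_samples,
    orientation_correct,
    anova_amplitudes,
)
from gatefret.io import write_results_json
from gatefret.model_selection import compare_k_fits, svd_components
from gatefret.ratchet_kinetics import (
    TwoStateModel,
    emulate_tirf,
    estimate_dwell_rates,
    simulate_two_state,
    trajectory_histogram,
)
from gatefret.ensemble_assays import fit_exponentials, fit_tight_binding
from gatefret.trace_analysis import select_smfret_trace

logger = logging.getLogger(__name__)

ALL_STAGES = ("traces", "histograms", "fit", "svd", "gillespie", "binding", "decay")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Seeded, serialisable description of one pipeline run."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    out_dir: str | None = None
    # histogram settings
    bin_min: float = -0.2
    bin_max: float = 1.2
    bin_width: float = 0.05
    n_per_replicate: int = 200
    n_replicates: int = 3
    # trace-stage settings
    n_traces: int = 50
    # kinetics settings
    total_time: float = 600.0
    dwell_total_time: float = 2000.0

    @property
    def bin_edges(self) -> np.ndarray:
        n = int(round((self.bin_max - self.bin_min) / self.bin_width))
        return np.linspace(self.bin_min, self.bin_max, n + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _stage_seed(config: RunConfig, stage: str) -> int:
    ss = np.random.SeedSequence([config.seed, ALL_STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return (and optionally write) results."""
    results: dict = {"seed": config.seed, "stages": list(config.stages)}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    samples = None
    hist_set = None
    try:
        for stage in config.stages:
            logger.info("running stage %s", stage)
            if stage == "traces":
                results["traces"] = _run_traces(config)
            elif stage == "histograms":
                samples = sd.sample_condition_set(
                    n_per_replicate=config.n_per_replicate,
                    n_replicates=config.n_replicates,
                    seed=_stage_seed(config, "histograms"))
                hist_set = histograms_from_samples(samples, config.bin_edges)
                results["histograms"] = {
                    cond: {"mean_total": average_replicates(reps).total}
                    for cond, reps in hist_set.items()}
            elif stage == "fit":
                if hist_set is None:
                    raise RuntimeError("'fit' requires the 'histograms' stage")
                results["fit"] = _run_fit(config, hist_set)
            elif stage == "svd":
                if hist_set is None:
                    raise RuntimeError("'svd' requires the 'histograms' stage")
                svd = svd_components(hist_set)
                rss = compare_k_fits(hist_set, k_values=(1, 2, 3),
                                     seed=_stage_seed(config, "svd"))
                results["svd"] = {
                    "n_significant": svd.n_significant,
                    "noise_floor": svd.noise_floor,
                    "singular_values": [float(s) for s in svd.singular_values[:6]],
                    "rss_per_k": {str(k): v for k, v in rss.items()},
                }
            elif stage == "gillespie":
                results["gillespie"] = _run_gillespie(config)
            elif stage == "binding":
                spec = sd.TitrationSpec(seed=_stage_seed(config, "binding"))
                fit = fit_tight_binding(sd.generate_titration(spec))
                results["binding"] = {"KD_nM": fit.KD, "Bmax": fit.Bmax,
                                      "F0": fit.F0, "true_KD_nM": spec.KD}
            elif stage == "decay":
                spec = sd.DecaySpec(rates=(0.5, 0.05), amplitudes=(0.6, 0.4),
                                    duration=120.0, noise_sd=0.005,
                                    seed=_stage_seed(config, "decay"))
                fit = fit_exponentials(sd.generate_decay(spec), n_components=2)
                results["decay"] = {
                    "rates_per_s": sorted(float(k) for k in fit.rates),
                    "t_half_s": fit.t_half}
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as exc:
        if out_dir:  # retain whatever was produced before the failure
            write_results_json(results, out_dir / "results_partial.json")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    if out_dir:
        write_results_json(results, out_dir / "results.json")
    return results


def _run_traces(config: RunConfig) -> dict:
    rng = np.random.default_rng(_stage_seed(config, "traces"))
    accepted, reasons = [], {}
    for _ in range(config.n_traces):
        e_true = float(np.clip(rng.normal(0.6, 0.1), 0.05, 0.95))
        params = sd.TraceParams(fret_efficiency_true=e_true,
                                seed=int(rng.integers(0, 2**31 - 1)),
                                accepted_fixture=False)
        trace = sd.generate_intensity_trace(params)
        sel = select_smfret_trace(trace)
        if sel.accepted:
            accepted.append((sel.observation.E, e_true))
        else:
            reasons[sel.reason] = reasons.get(sel.reason, 0) + 1
    out = {"n_traces": config.n_traces, "n_accepted": len(accepted),
           "rejections": reasons}
    if accepted:
        err = [e - t for e, t in accepted]
        out["mean_E_error"] = float(np.mean(err))
    return out


def _run_fit(config: RunConfig, hist_set) -> dict:
    fit = fit_staged_mixture(hist_set, seed=_stage_seed(config, "fit"))
    means, sems = anova_amplitudes(fit.condition_amplitudes)
    alone = means["alone"]
    corrected = {c: [float(x) for x in orientation_correct(m, alone)]
                 for c, m in means.items()}
    return {
        "component_means": [c.mean for c in fit.components],
        "component_widths": [c.width for c in fit.components],
        "amplitude_means": {c: [float(x) for x in m] for c, m in means.items()},
        "amplitude_sems": {c: [float(x) for x in s] for c, s in sems.items()},
        "orientation_corrected": corrected,
        "rss_per_stage": {str(k): v for k, v in fit.rss_per_stage.items()},
        "stage4_consistent": fit.stage4_consistent,
    }


def _run_gillespie(config: RunConfig) -> dict:
    seed = _stage_seed(config, "gillespie")
    model = TwoStateModel(total_time=config.total_time)
    traj = simulate_two_state(model, seed=seed)
    trace = emulate_tirf(traj, model, seed=seed + 1)
    hist = trajectory_histogram(trace, config.bin_edges)
    long_model = TwoStateModel(total_time=config.dwell_total_time)
    long_traj = simulate_two_state(long_model, seed=seed + 2)
    (k_high, se_high), (k_low, se_low) = estimate_dwell_rates(long_traj)
    occupancy = float(np.mean(long_traj.states))
    modal_bin = float(hist.bin_centres[int(np.argmax(hist.frequencies))])
    return {
        "k_high_exit_per_s": k_high, "k_high_exit_se": se_high,
        "k_low_exit_per_s": k_low, "k_low_exit_se": se_low,
        "high_state_occupancy": occupancy,
        "modal_bin_centre": modal_bin,
    }
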