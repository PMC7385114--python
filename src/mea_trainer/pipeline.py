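"""End-to-end orchestration: simulate -> detect -> bursts -> spectra ->
synchrony -> evoked, driven by one YAML config, with a run manifest.

Every stage writes its tables under the output directory and appends a
manifest entry (parameters, outputs, SHA-256 hashes, warnings), so a rerun
with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .bursts import BurstParams, burst_statistics, detect_bursts
from .detection import (
    DetectionConfig,
    active_electrodes,
    calibrate_threshold_on_ground,
    detect_spikes,
    estimate_noise,
    highpass_filter,
    validate_waveforms,
)
from .errors import DependencyError, ValidationError
from .evoked import evoked_rates, quiescence_duration
from .protocol import RecordingStimPlan, build_recording_plan, epochs_from_plan
from .simulate import SyntheticNetworkConfig, WaveformTemplate, render_raw, simulate_spikes
from .spectral import SpectralConfig, aggregate_spectra, band_power, electrode_spectrograms
from .synchrony import SynchronyConfig, pre_post_ratio, synchrony_matrix, timecourse_synchrony
from .types import SpikeTrainSet, standard_layout

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

log = logging.getLogger("mea_trainer")

ALL_STAGES = ("simulate", "detect", "bursts", "spectra", "synchrony", "evoked")


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration: stages to run, per-stage parameters, seed."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict = dataclasses.field(default_factory=dict)
    stim_plan: dict | None = None
    render: dict | None = None  # if set, raw traces are synthesized + detected
    detection: dict = dataclasses.field(default_factory=dict)
    bursts: dict = dataclasses.field(default_factory=dict)
    spectra: dict = dataclasses.field(default_factory=dict)
    synchrony: dict = dataclasses.field(default_factory=dict)
    evoked: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValidationError(f"unknown stages: {sorted(bad)}")


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "outdir" not in raw:
        raise ValidationError("run config must declare an outdir")
    raw.setdefault("stages", list(ALL_STAGES))
    raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stim_plan(config: RunConfig, duration_s: float) -> RecordingStimPlan | None:
    if config.stim_plan is None:
        return None
    d = dict(config.stim_plan)
    d.setdefault("recording_duration_s", duration_s)
    return build_recording_plan(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "warnings": []}

    def record_stage(name: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "parameters": params,
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
        log.info("stage %s: wrote %s", name, ", ".join(p.name for p in outputs))

    spikes: SpikeTrainSet | None = None
    truth = None
    plan: RecordingStimPlan | None = None

    if "simulate" in config.stages:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        duration = sim_kwargs.get("duration_s", SyntheticNetworkConfig.duration_s)
        plan = _stim_plan(config, duration)
        sim_cfg = SyntheticNetworkConfig(stim_plan=plan, **sim_kwargs)
        ground = config.render.get("ground_id") if config.render else None
        layout = standard_layout(sim_cfg.n_electrodes, ground_id=ground)
        spikes, truth = simulate_spikes(sim_cfg, layout)
        spike_path = outdir / "spikes_true.csv"
        mio.write_spike_csv(spikes, spike_path)
        truth_path = outdir / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "burst_event_times_s": truth.burst_event_times.tolist(),
                    "label_counts": truth.label_counts(),
                    "n_removed_by_refractory": int(
                        sum(v.size for v in truth.removed_times.values())
                    ),
                },
                indent=2,
            )
        )
        record_stage("simulate", sim_kwargs, [spike_path, truth_path])

        if config.render is not None:
            render_kwargs = {
                k: v for k, v in config.render.items() if k != "ground_id"
            }
            render_kwargs.setdefault("seed", config.seed)
            raw = render_raw(
                spikes,
                WaveformTemplate.default(
                    render_kwargs.get("sampling_rate_hz", 10_000.0)
                ),
                artifact_plan=plan,
                **render_kwargs,
            )
            raw_path = outdir / "raw.h5"
            mio.write_raw_hdf5(raw, raw_path)
            record_stage("render", render_kwargs, [raw_path])

    if "detect" in config.stages:
        raw_path = outdir / "raw.h5"
        if not raw_path.exists():
            raise DependencyError("detect stage requires rendered raw data (stage: simulate/render)")
        raw = mio.read_raw_hdf5(raw_path)
        det_cfg = DetectionConfig(**config.detection)
        filtered = highpass_filter(raw, det_cfg)
        if raw.layout.ground_id is not None:
            det_cfg = calibrate_threshold_on_ground(filtered, det_cfg)
        noise = estimate_noise(filtered, det_cfg.noise_estimator)
        detected = validate_waveforms(
            filtered, detect_spikes(filtered, noise, det_cfg), det_cfg, noise
        )
        spikes = detected
        spike_path = outdir / "spikes_detected.csv"
        mio.write_spike_csv(detected, spike_path)
        report = {
            "threshold_multiplier": det_cfg.threshold_multiplier,
            "noise_sd_uv": noise.sd_uv,
            "counts": detected.counts(),
            "active": active_electrodes(detected, det_cfg),
        }
        report_path = outdir / "detection_report.json"
        report_path.write_text(json.dumps(report, indent=2))
        record_stage("detect", dataclasses.asdict(det_cfg), [spike_path, report_path])

    if spikes is None and any(
        s in config.stages for s in ("bursts", "spectra", "synchrony", "evoked")
    ):
        raise DependencyError("downstream stages need spikes (enable simulate or detect)")

    analyzed: list[str] = []
    if spikes is not None:
        det_cfg = DetectionConfig(**config.detection)
        active = active_electrodes(spikes, det_cfg)
        analyzed = [e for e in active if e != spikes.layout.ground_id] or list(
            spikes.layout.recording_ids()
        )

    if "bursts" in config.stages:
        params = BurstParams(**config.bursts)
        burst_rows, summary_rows = [], []
        for eid in analyzed:
            bs = detect_bursts(spikes.trains[eid], params, electrode_id=eid)
            burst_rows += [
                {
                    "electrode_id": eid,
                    "start_s": b.start_s,
                    "end_s": b.end_s,
                    "n_spikes": b.n_spikes,
                    "duration_s": b.duration_s,
                }
                for b in bs
            ]
            summary_rows.append(
                {"electrode_id": eid}
                | burst_statistics(bs, spikes.trains[eid], spikes.duration_s)
            )
        bpath = outdir / "bursts.csv"
        pd.DataFrame(
            burst_rows,
            columns=["electrode_id", "start_s", "end_s", "n_spikes", "duration_s"],
        ).to_csv(bpath, index=False, float_format="%.9f")
        spath = outdir / "burst_summary.csv"
        pd.DataFrame(summary_rows).to_csv(spath, index=False, float_format="%.9f")
        record_stage("bursts", dataclasses.asdict(params), [bpath, spath])

    if "spectra" in config.stages:
        spec_kwargs = dict(config.spectra)
        spec_kwargs.setdefault(
            "analysis_end_s", min(240.0, spikes.duration_s)
        )
        spec_cfg = SpectralConfig(**spec_kwargs)
        per_e = electrode_spectrograms(spikes, analyzed, spec_cfg)
        culture = aggregate_spectra(per_e, "sum_electrodes")
        mat_path = outdir / "spectrogram.csv"
        pd.DataFrame(
            culture.values,
            columns=[f"{f:.6g}" for f in culture.frequencies_hz],
        ).to_csv(mat_path, index_label="window", float_format="%.9g")
        bands = {
            "sum_band": spec_cfg.sum_band,
            "report_band": spec_cfg.report_band,
        }
        band_rows = [
            {
                "band": name,
                "lo_hz": lo,
                "hi_hz": hi,
                "power": band_power(culture, (lo, hi)),
            }
            for name, (lo, hi) in bands.items()
        ]
        band_path = outdir / "band_power.csv"
        mio.write_results_table(band_rows, band_path)
        record_stage("spectra", spec_kwargs, [mat_path, band_path])

    if "synchrony" in config.stages:
        syn_cfg = SynchronyConfig(**config.synchrony)
        ids = analyzed if syn_cfg.use_active_only else list(spikes.layout.recording_ids())
        matrix = synchrony_matrix(spikes, ids, syn_cfg)
        mat_path = outdir / "synchrony_matrix.csv"
        pd.DataFrame(matrix.values, index=ids, columns=ids).to_csv(
            mat_path, float_format="%.9g"
        )
        tc = timecourse_synchrony(spikes, ids, syn_cfg)
        tc_path = outdir / "synchrony_timecourse.csv"
        pd.DataFrame(
            {"segment_start_s": tc["segment_starts_s"], "chi": tc["chi_series"]}
        ).to_csv(tc_path, index=False, float_format="%.9g")
        summary = {"chi_mean": matrix.mean, "n_electrodes": len(ids)}
        if plan is None and config.stim_plan is not None:
            plan = _stim_plan(config, spikes.duration_s)
        if plan is not None and plan.n_blocks:
            window = config.evoked.get("window_s", 20.0)
            ratios = []
            for k, block in enumerate(plan.block_intervals()):
                try:
                    ratios.append(
                        {"block": k} | pre_post_ratio(tc, block, window_s=window)
                    )
                except ValidationError as exc:
                    manifest["warnings"].append(f"synchrony ratio block {k}: {exc}")
            summary["pre_post_ratios"] = ratios
        sum_path = outdir / "synchrony_summary.json"
        sum_path.write_text(json.dumps(summary, indent=2))
        record_stage(
            "synchrony", dataclasses.asdict(syn_cfg), [mat_path, tc_path, sum_path]
        )

    if "evoked" in config.stages:
        if plan is None:
            plan = _stim_plan(config, spikes.duration_s)
        if plan is None or not plan.n_blocks:
            raise DependencyError("evoked stage requires a stimulation plan (stim_plan)")
        window = config.evoked.get("window_s", 20.0)
        epochs = epochs_from_plan(plan, pre_window_s=window, post_window_s=window)
        records, per_table = evoked_rates(spikes, epochs, analyzed)
        enriched = []
        for rec, block in zip(records, plan.block_intervals()):
            q, capped = (float("nan"), False)
            if rec.fr_pre_hz > 0:
                q, capped = quiescence_duration(
                    spikes,
                    block,
                    rec.fr_pre_hz,
                    analyzed,
                    smoothing_bin_s=config.evoked.get("smoothing_bin_s", 1.0),
                    recovery_fraction=config.evoked.get("recovery_fraction", 0.5),
                    cap_s=config.evoked.get("cap_s"),
                )
                if capped:
                    manifest["warnings"].append(
                        f"quiescence capped for block {rec.block}"
                    )
            enriched.append(
                {
                    "block": rec.block,
                    "fr_pre_hz": rec.fr_pre_hz,
                    "fr_stim_hz": rec.fr_stim_hz,
                    "fr_post_hz": rec.fr_post_hz,
                    "ratio_stim": rec.ratio_stim,
                    "ratio_post": rec.ratio_post,
                    "quiescence_s": q,
                    "quiescence_capped": capped,
                }
            )
        ev_path = outdir / "evoked.csv"
        mio.write_results_table(enriched, ev_path)
        per_path = outdir / "evoked_per_electrode.csv"
        per_table.to_csv(per_path, index=False, float_format="%.9g")
        record_stage("evoked", dict(config.evoked), [ev_path, per_path])

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
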