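"""End-to-end orchestration with config validation and provenance.

``run_pipeline`` executes preprocess -> movement RDMs -> model timecourses
(+ bootstrap bands) -> time-time maps (with/without covariates) -> cluster
inference -> ROI commonality on one study's inputs, writing every
intermediate with a manifest (input hashes, config, seed, package version).
Inputs are either file paths (trials/stimuli CSV, neural/ROI containers)
or generated on the fly from a simulation config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .commonality import commonality_map
from .inference import cluster_permutation_test, resample_band
from .rdm import RDMSeries, binary_model_rdm, execution_time_rdm, movement_rdm_series
from .similarity import time_time_map, model_timecourse
from .synthetic import SimulationConfig, make_stimuli, simulate_neural_rdms, simulate_roi_rdms, simulate_trajectories
from .trajectories import (
    StimulusSet,
    average_trajectories,
    filter_participants,
    filter_trials,
    load_trials,
    mirror_to_canonical,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage, self.code = stage, code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # inputs: either paths ...
    trials_csv: str | None = None
    stimuli_csv: str | None = None
    neural_h5: list[str] = field(default_factory=list)
    roi_h5: list[str] = field(default_factory=list)
    covariate_h5: list[str] = field(default_factory=list)
    # ... or a simulation block (dict of SimulationConfig overrides)
    simulate: dict | None = None
    # preprocessing thresholds
    min_recorded_ms: float = 100.0
    min_displacement_px: float = 50.0
    min_accuracy: float = 0.70
    # analysis settings
    region: list | None = None  # [row_category, col_category] or None
    movement_step_ms: int = 10  # movement lattice for time-time inference
    n_resamples: int = 1000
    n_perm: int = 1000
    alpha_cluster: float = 0.05
    alpha_fwe: float = 0.05
    tail: str = "positive"
    with_execution_time_covariate: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("trials_csv", "stimuli_csv"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineError("validate", "missing_input", f"{name} required")
                if not Path(p).exists():
                    raise PipelineError("validate", "input_not_found", f"{name}: {p}")
            for p in [*self.neural_h5, *self.roi_h5]:
                if not Path(p).exists():
                    raise PipelineError("validate", "input_not_found", str(p))
        for p in self.covariate_h5:
            if not Path(p).exists():
                raise PipelineError("validate", "covariate_not_found", str(p))
        if self.tail not in ("positive", "two-sided"):
            raise PipelineError("validate", "bad_value", f"tail={self.tail!r}")
        for name in ("min_accuracy", "alpha_cluster", "alpha_fwe"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PipelineError("validate", "bad_value", f"{name}={v}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``<out_dir>/manifest.json``)."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "version": __version__,
        "inputs": {},
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = SimulationConfig.miniature(**config.simulate)
            stimuli = make_stimuli(sim)
            trials_df, traj_truth = simulate_trajectories(stimuli, sim, config.seed)
            neural, _ = simulate_neural_rdms(stimuli, sim, config.seed)
            rois, roi_truth = simulate_roi_rdms(stimuli, sim, config.seed)
            trials = load_trials(trials_df)
            manifest["inputs"]["simulated"] = {
                "seed": config.seed,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(sim).items()},
            }
        else:
            stimuli = StimulusSet.from_csv(config.stimuli_csv)
            trials = load_trials(config.trials_csv)
            neural = [tio.load_rdm_series(p) for p in config.neural_h5]
            rois = [tio.load_rdm(p) for p in config.roi_h5]
            for name in ("trials_csv", "stimuli_csv"):
                manifest["inputs"][name] = _sha256(Path(getattr(config, name)))
            for p in [*config.neural_h5, *config.roi_h5, *config.covariate_h5]:
                manifest["inputs"][str(p)] = _sha256(Path(p))
        extra_covs = [tio.load_rdm(p) for p in config.covariate_h5]
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "load_failed", str(e)) from e
    manifest["stages"].append(stage)

    # ---- preprocess -------------------------------------------------------
    stage = "preprocess"
    try:
        kept, trial_report = filter_trials(
            trials, config.min_recorded_ms, config.min_displacement_px
        )
        kept, part_report = filter_participants(kept, config.min_accuracy)
        kept_canonical = mirror_to_canonical(kept, stimuli)
        means = average_trajectories(kept_canonical, stimuli)
        tio.save_means(out / "means.h5", means)
        tio.write_json(
            out / "exclusions.json",
            {"trials": trial_report.to_dict(), "participants": part_report.to_dict()},
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "preprocess_failed", str(e)) from e
    manifest["stages"].append(stage)

    # ---- movement RDMs + model timecourses --------------------------------
    stage = "rdm"
    try:
        mov = movement_rdm_series(means)
        tio.save_rdm_series(out / "mov_rdms.h5", mov)
        task = binary_model_rdm(stimuli, "task")
        look = binary_model_rdm(stimuli, "lookalike")
        tc_task = model_timecourse(mov, task)
        tc_look = model_timecourse(mov, look)
        np.savetxt(
            out / "model_timecourses.csv",
            np.column_stack([mov.times, tc_task.rho, tc_look.rho]),
            delimiter=",",
            header="time_ms,rho_task,rho_lookalike",
            comments="",
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "rdm_failed", str(e)) from e
    manifest["stages"].append(stage)

    # ---- bootstrap bands --------------------------------------------------
    stage = "bands"
    try:
        band = resample_band(
            neural,
            [task, look],
            mode="neural_participants",
            n_resamples=config.n_resamples,
            seed=config.seed,
        )
        np.savetxt(
            out / "neural_model_bands.csv",
            np.column_stack(
                [band.times, band.point.T, band.low.T, band.high.T]
            ),
            delimiter=",",
            header="time_ms,rho_task,rho_look,low_task,low_look,high_task,high_look",
            comments="",
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "bands_failed", str(e)) from e
    manifest["stages"].append(stage)

    # ---- time-time maps + clusters ---------------------------------------
    stage = "timetime"
    try:
        step = config.movement_step_ms
        mov_coarse = mov.subsample(
            np.arange(step, mov.times.max() + 1e-9, step, dtype=float)
        )
        region = tuple(config.region) if config.region else None
        exec_cov = []
        if config.with_execution_time_covariate:
            exec_cov = [execution_time_rdm(kept, stimuli)]
        variants = {
            "raw": [],
            "task": [task],
            "controls": exec_cov + extra_covs,
            "task_controls": [task] + exec_cov + extra_covs,
        }
        cluster_summaries = {}
        for name, covs in variants.items():
            tmap = time_time_map(
                mov_coarse, neural, covariates=covs, region=region, stimuli=stimuli
            )
            tio.save_timetime(out / f"timetime_{name}.h5", tmap)
            res = cluster_permutation_test(
                tmap.values,
                alpha_cluster=config.alpha_cluster,
                alpha_fwe=config.alpha_fwe,
                n_perm=config.n_perm,
                tail=config.tail,
                seed=config.seed,
            )
            cluster_summaries[name] = res.summary()
        tio.write_json(out / "clusters.json", cluster_summaries)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "timetime_failed", str(e)) from e
    manifest["stages"].append(stage)

    # ---- commonality ------------------------------------------------------
    stage = "commonality"
    try:
        if rois:
            cmap = commonality_map(
                mov_coarse, neural, rois, extra_covariates=[task]
            )
            comm_summary = {}
            for r, roi_name in enumerate(cmap.roi_labels):
                res = cluster_permutation_test(
                    cmap.values[r],
                    alpha_cluster=config.alpha_cluster,
                    alpha_fwe=config.alpha_fwe,
                    n_perm=config.n_perm,
                    tail=config.tail,
                    seed=config.seed,
                )
                summary = res.summary()
                gm = np.nanmean(cmap.values[r], axis=0)
                summary["mean_C_in_sig"] = (
                    float(np.nanmean(gm[res.sig_mask])) if res.sig_mask.any() else None
                )
                comm_summary[roi_name] = summary
            tio.write_json(out / "commonality.json", comm_summary)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "commonality_failed", str(e)) from e
    manifest["stages"].append(stage)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest["outputs"] = {
        name: _sha256(out / name) for name in outputs
    }
    tio.write_json(out / "manifest.json", manifest)
    return manifest
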