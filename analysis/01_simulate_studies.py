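#!/usr/bin/env python
"""Generate the two synthetic studies the downstream analyses consume.

Writes, for a face-like and an animal-like desk-scale study, the raw
cursor logs (long-format CSV), stimulus metadata, per-participant neural
RDM series and static ROI RDMs, plus the planted ground truth, under
scratch/sim_<study>/.  Desk scale keeps the paper-scale structure (three
matched categories plus fillers, four blocks with a box swap, 4 trials per
image) at a size every later script can re-run in seconds.
"""

import dataclasses
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import trajrsa as T
from trajrsa import io as tio

SEED = 7
ROOT = Path(__file__).resolve().parents[1]

CONFIGS = {
    "face": T.SimulationConfig.miniature(
        study="face", n_per_category=8, n_filler=8, n_participants_traj=24,
        n_participants_neural=16, lookalike_pull=0.12, lookalike_delay_ms=75.0,
        roi_labels=("FFA", "OFA", "LO", "PPA"), roi_weights=(0.8, 0.6, 0.3, 0.15),
    ),
    "animal": T.SimulationConfig.miniature(
        study="animal", n_per_category=8, n_filler=8, n_participants_traj=24,
        n_participants_neural=16, neural_step_ms=4.0, lookalike_pull=0.45,
        lookalike_delay_ms=110.0, neural_task_weight=0.18,
        neural_lookalike_weight=0.35,
        roi_labels=("EVC", "postVTC", "antVTC"), roi_weights=(0.3, 0.5, 0.8),
    ),
}


def main() -> None:
    for study, cfg in CONFIGS.items():
        out = ROOT / "scratch" / f"sim_{study}"
        out.mkdir(parents=True, exist_ok=True)
        stimuli = T.make_stimuli(cfg)
        stimuli.to_frame().to_csv(out / "stimuli.csv", index=False)
        df, truth = T.simulate_trajectories(stimuli, cfg, SEED)
        df.to_csv(out / "trials.csv", index=False)
        neural, _ = T.simulate_neural_rdms(stimuli, cfg, SEED)
        for s in neural:
            tio.save_rdm_series(out / f"{s.source}.h5", s)
        rois, _ = T.simulate_roi_rdms(stimuli, cfg, SEED)
        for r in rois:
            tio.save_rdm(out / f"roi_{r.source}.h5", r)
        tio.write_json(
            out / "ground_truth.json",
            {
                "seed": SEED,
                "lag_ms": truth.lag_ms,
                "low_accuracy_participants": truth.low_accuracy_participants,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(cfg).items()},
            },
        )
        n_trials = df.groupby(["participant_id", "trial_index"]).ngroups
        print(
            f"[{study}] {len(stimuli.analysis_ids)} analysis images "
            f"(+{len(stimuli) - len(stimuli.analysis_ids)} fillers), "
            f"{cfg.n_participants_traj} movement participants, "
            f"{n_trials} trials, {len(neural)} neural participants, "
            f"{len(rois)} ROIs -> {out}"
        )


if __name__ == "__main__":
    main()
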